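"""Growing and exporting a latent class tree.

A latent class tree is built divisively: the full sample forms the root, a
root split into ``root_K`` classes is estimated on the unweighted data, and
every resulting node is then tested recursively for a further (by default
binary) split. Cases are carried into child nodes by *proportional
assignment*: each case is present at every node with a weight equal to the
product of the posterior membership probabilities along the path from the
root, so the per-case weights of the children of a node always sum to the
node's own weight. A candidate split is accepted when the information
criterion (BIC by default) of the k-class model fitted to the node-weighted
data is lower than that of the one-class model.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import CategoricalDataset
from .lc import FitResult, IndicatorModel, LCParameters

__all__ = [
    "TreeNode",
    "LatentClassTree",
    "SplitDecision",
    "child_weights",
    "try_split",
    "grow_tree",
    "order_children",
    "node_profile",
]


@dataclass
class SplitDecision:
    """Outcome of testing one node for a split."""

    accepted: bool
    criterion: str
    model: FitResult | None = None       # the k-class candidate
    null_model: FitResult | None = None  # the 1-class reference
    reason: str = ""

    @property
    def criterion_values(self) -> dict:
        out = {}
        if self.null_model is not None:
            out["1"] = float(getattr(self.null_model, self.criterion))
        if self.model is not None:
            out[str(self.model.n_classes)] = float(
                getattr(self.model, self.criterion)
            )
        return out


@dataclass
class TreeNode:
    """One node of a latent class tree.

    ``label`` is the digit-string path from the root (root children are
    ``"1"``, ``"2"``, ...; their children append a digit, e.g. ``"21"``). The
    root itself has the empty label. ``weights`` is the full-length case
    weight vector at this node; ``size`` is its sum.
    """

    label: str
    weights: np.ndarray
    depth: int
    split: SplitDecision | None = None
    children: list["TreeNode"] = field(default_factory=list)
    class_index: int = 0  # class in the parent's split model this node came from

    @property
    def size(self) -> float:
        return float(self.weights.sum())

    @property
    def split_model(self) -> FitResult | None:
        if self.split is not None and self.split.accepted:
            return self.split.model
        return None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def display_label(self) -> str:
        return self.label if self.label else "root"


@dataclass
class LatentClassTree:
    """A grown tree plus the settings that produced it."""

    root: TreeNode
    n_total: int
    settings: dict = field(default_factory=dict)

    @property
    def leaves(self) -> list[TreeNode]:
        return [n for n in self.nodes() if n.is_leaf]

    def nodes(self) -> list[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(reversed(n.children))
        return out

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "settings": {k: v for k, v in self.settings.items()},
            "root": _node_dict(self.root),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def to_dot(self) -> str:
        """Graphviz DOT rendering with size-annotated nodes."""
        lines = ["digraph lctree {", '  node [shape=box];']
        for node in self.nodes():
            nid = "n_" + (node.label or "root")
            lines.append(
                f'  {nid} [label="{node.display_label()}\\nn={node.size:.1f}"];'
            )
            for child in node.children:
                lines.append(f'  {nid} -> n_{child.label};')
        lines.append("}")
        return "\n".join(lines)


def child_weights(parent_weights: np.ndarray, posteriors: np.ndarray) -> list[np.ndarray]:
    """Per-child case weights: parent weight times child posterior.

    Because posterior rows sum to 1, the returned vectors sum case-wise to the
    parent weights — weight mass is conserved down the tree.
    """
    w = np.asarray(parent_weights, dtype=float)
    post = np.asarray(posteriors, dtype=float)
    if post.ndim != 2 or post.shape[0] != w.shape[0]:
        raise ValueError("posteriors must be (N, K) matching the weight vector")
    return [w * post[:, k] for k in range(post.shape[1])]


def _class_sort_key(params, k: int):
    """Deterministic tie-break key: the class's parameter profile."""
    if isinstance(params, LCParameters):
        return tuple(float(x) for p in params.response_probs for x in p[k])
    logits = getattr(params, "logits", None)
    if logits is not None:
        return tuple(float(x) for b in logits for x in b[k])
    return (k,)


def try_split(
    data: CategoricalDataset,
    node: TreeNode,
    *,
    model=None,
    criterion: str = "bic",
    k_split: int = 2,
    seed: int | None = None,
    min_size: float = 0.0,
    ic_mode: str = "total",
    **fit_options,
) -> SplitDecision:
    """Test whether splitting ``node`` into ``k_split`` classes is warranted.

    Fits 1-class and ``k_split``-class models on the data weighted by the
    node's weights and accepts the split when the chosen criterion of the
    k-class model is lower. ``ic_mode`` selects the n in the BIC penalty:
    ``"total"`` uses the root sample size (the printed-formula convention),
    ``"node"`` the node's effective size.
    """
    if criterion not in ("bic", "aic"):
        raise ValueError("criterion must be 'bic' or 'aic'")
    if model is None:
        model = IndicatorModel()
    if node.size <= 0:
        return SplitDecision(False, criterion, reason="empty node")
    if node.size < min_size:
        return SplitDecision(
            False, criterion,
            reason=f"node size {node.size:.2f} below minimum {min_size:.2f}",
        )
    p_k = model.n_parameters(data, k_split)
    if node.size < p_k:
        warnings.warn(
            f"node {node.display_label()} has effective size {node.size:.2f} "
            f"< {p_k} parameters; split rejected", stacklevel=2,
        )
        return SplitDecision(False, criterion, reason="fewer effective cases than parameters")
    ic_n = None if ic_mode == "total" else node.size
    s1, s2 = _split_seeds(seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # boundary warnings on tiny nodes
        fit1 = model.fit(data, 1, weights=node.weights, seed=s1,
                         ic_sample_size=ic_n, **fit_options)
        fitk = model.fit(data, k_split, weights=node.weights, seed=s2,
                         ic_sample_size=ic_n, **fit_options)
    accepted = getattr(fitk, criterion) < getattr(fit1, criterion)
    return SplitDecision(accepted, criterion, model=fitk, null_model=fit1,
                         reason="" if accepted else f"{criterion} not improved")


def _split_seeds(seed: int | None) -> tuple[int, int]:
    ss = np.random.SeedSequence(seed).spawn(2)
    return tuple(int(s.generate_state(1)[0] % (2**31)) for s in ss)


def _node_seed(master: int | None, label: str) -> int:
    # labels contain only digits 1..9, so prefixing "1" makes the key injective
    key = int("1" + label)
    ss = np.random.SeedSequence([0 if master is None else int(master), key])
    return int(ss.generate_state(1)[0] % (2**31))


def order_children(node: TreeNode) -> TreeNode:
    """Order children by size descending and reassign path labels.

    Exact size ties are broken by lexicographic comparison of the class
    parameter profiles, so relabeling is deterministic. Idempotent.
    """
    if not node.children:
        return node
    params = node.split_model.params if node.split_model is not None else None
    node.children.sort(
        key=lambda c: (
            -c.size,
            _class_sort_key(params, c.class_index) if params is not None
            else (c.class_index,),
        ),
    )
    for pos, child in enumerate(node.children):
        _relabel(child, node.label + str(pos + 1))
    return node


def _relabel(node: TreeNode, label: str) -> None:
    node.label = label
    for pos, child in enumerate(node.children):
        _relabel(child, label + str(pos + 1))


def node_profile(node: TreeNode):
    """Parameters of the node's split model (conditional on the parent).

    Returns the fitted parameter object: class proportions plus, for the
    indicator model, per-item conditional response probabilities (for the
    ranking model, class-specific logits). Raises on an unsplit node.
    """
    if node.split_model is None:
        raise ValueError(f"node {node.display_label()} has no accepted split")
    return node.split_model.params


def grow_tree(
    data: CategoricalDataset,
    root_K: int = 2,
    *,
    criterion: str = "bic",
    model=None,
    max_depth: int = 10,
    min_split_fraction: float = 0.01,
    k_split: int = 2,
    seed: int | None = None,
    ic_mode: str = "total",
    root_fits: tuple[FitResult, FitResult] | None = None,
    **fit_options,
) -> LatentClassTree:
    """Grow a latent class tree.

    The root is tested for a split into ``root_K`` classes (gated by the same
    criterion comparison against the one-class model); accepted children are
    then tested breadth-first for ``k_split``-class (default binary) splits
    until no further split is accepted, a node falls below
    ``min_split_fraction`` of the sample, or ``max_depth`` is reached.
    Children are ordered by size descending and labeled by their path.

    ``root_fits`` optionally supplies prefitted (1-class, root_K-class) models
    for the root — e.g. the rows of a fit table used to choose ``root_K`` —
    so the tree reuses them instead of refitting.
    """
    if root_K < 1:
        raise ValueError("root_K must be >= 1")
    if model is None:
        model = IndicatorModel()
    n = data.n_cases
    min_size = min_split_fraction * float(data.weights.sum())
    root = TreeNode(label="", weights=data.weights.copy(), depth=0)
    settings = {
        "root_K": root_K, "criterion": criterion, "k_split": k_split,
        "max_depth": max_depth, "min_split_fraction": min_split_fraction,
        "seed": seed, "ic_mode": ic_mode,
    }
    tree = LatentClassTree(root=root, n_total=n, settings=settings)

    if root_K == 1:
        root.split = SplitDecision(False, criterion, reason="root_K=1 requested")
        return tree

    if root_fits is not None:
        fit1, fitk = root_fits
        if fitk.n_classes != root_K:
            raise ValueError("supplied root fit does not have root_K classes")
        accepted = getattr(fitk, criterion) < getattr(fit1, criterion)
        root.split = SplitDecision(accepted, criterion, model=fitk,
                                   null_model=fit1,
                                   reason="" if accepted else f"{criterion} not improved")
    else:
        root.split = try_split(
            data, root, model=model, criterion=criterion, k_split=root_K,
            seed=_node_seed(seed, root.label), min_size=min_size,
            ic_mode=ic_mode, **fit_options,
        )

    queue: list[TreeNode] = []
    if root.split.accepted:
        _attach_children(root, root.split.model)
        queue.extend(root.children)

    while queue:
        node = queue.pop(0)
        if node.depth >= max_depth:
            warnings.warn(
                f"max_depth={max_depth} reached at node {node.label}; "
                "growth stopped there", stacklevel=2,
            )
            continue
        node.split = try_split(
            data, node, model=model, criterion=criterion, k_split=k_split,
            seed=_node_seed(seed, node.label), min_size=min_size,
            ic_mode=ic_mode, **fit_options,
        )
        if node.split.accepted:
            _attach_children(node, node.split.model)
            queue.extend(node.children)
    return tree


def _attach_children(node: TreeNode, fit: FitResult) -> None:
    for k, w in enumerate(child_weights(node.weights, fit.posteriors)):
        node.children.append(
            TreeNode(label="?", weights=w, depth=node.depth + 1, class_index=k)
        )
    order_children(node)


def _node_dict(node: TreeNode) -> dict:
    d: dict = {
        "label": node.display_label(),
        "size": node.size,
        "depth": node.depth,
    }
    if node.split is not None:
        d["split"] = {
            "accepted": node.split.accepted,
            "criterion": node.split.criterion,
            "criterion_values": node.split.criterion_values,
            "reason": node.split.reason,
        }
    if node.split_model is not None:
        params = node.split_model.params
        profile = {"proportions": params.proportions.tolist()}
        if isinstance(params, LCParameters):
            profile["response_probs"] = [p.tolist() for p in params.response_probs]
        elif hasattr(params, "logits"):
            profile["logits"] = [b.tolist() for b in params.logits]
        d["profile"] = profile
    d["children"] = [_node_dict(c) for c in node.children]
    return d
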