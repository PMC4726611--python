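"""Binary classification tree for flake production behaviors.

A CART-style tree is grown on labelled, size-standardized flakes by recursive
binary partitioning (Gini impurity by default). The split convention is fixed:
a flake whose measurement is **equal to or larger than** a node's threshold
moves to the ``ge`` branch, otherwise to the ``lt`` branch.

A fully grown tree classifies its own training set (nearly) perfectly but
overfits. The tree is therefore *trimmed*: weakest-link (cost-complexity)
pruning generates the nested sequence of candidate subtrees, each candidate is
scored on a disjoint holdout set by repeated random subsampling, and the
subtree with the fewest terminal nodes among those attaining the minimum mean
misclassification rate is selected — the most economical tree.

Because even the trimmed tree errs, each classification carries a quantified
uncertainty: the misclassification matrix gives, for every *classified*
behavior, the empirical distribution of *true* behaviors among test flakes
receiving that classification. These row probabilities propagate into
assemblage-composition bounds downstream.
"""

from __future__ import annotations

import copy
import json
import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, ParameterError
from .morphometrics import STANDARDIZED_MEASURES
from .simulate import BEHAVIORS

#: Default classifier features: the six standardized shape measures plus the
#: two cortex percentages.
DEFAULT_FEATURES: tuple[str, ...] = STANDARDIZED_MEASURES + (
    "platform_cortex", "dorsal_cortex",
)


@dataclass
class TreeNode:
    """One node of the behavior tree.

    Internal nodes carry a feature name and threshold with ``ge``/``lt``
    children; every node also carries the statistics it would have as a leaf
    (training class probabilities and majority class), which is what a
    pruned-to-leaf node predicts.
    """

    node_id: int
    n_train: int
    class_probs: dict[str, float]
    predicted: str
    feature: str | None = None
    threshold: float | None = None
    ge: "TreeNode | None" = None
    lt: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def n_leaves(self) -> int:
        if self.is_leaf:
            return 1
        return self.ge.n_leaves() + self.lt.n_leaves()

    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(self.ge.depth(), self.lt.depth())


@dataclass
class TrimCurve:
    """Holdout misclassification rate as a function of tree size."""

    n_leaves: list[int]
    rates: list[float]
    chosen_size: int


@dataclass
class MisclassMatrix:
    """Per classified-behavior distribution of true behaviors (percent).

    ``table`` rows are classified behaviors (or individual leaves when built
    per-leaf), columns the four true behaviors; each defined row sums to 100.
    Classified behaviors to which no test flake was assigned are listed in
    ``undefined`` and their rows are NaN, never zero-filled.
    """

    table: pd.DataFrame
    counts: pd.DataFrame
    undefined: list[str] = field(default_factory=list)

    def row(self, classified: str) -> pd.Series:
        return self.table.loc[classified]


def _gini(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(1.0 - np.sum(p * p))


def _entropy(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-np.sum(p * np.log2(p)))


_IMPURITY = {"gini": _gini, "entropy": _entropy}


def _best_split(X: np.ndarray, y: np.ndarray, n_classes: int, min_leaf: int,
                criterion: str):
    """Exhaustive search for the impurity-minimizing axis-aligned split.

    Returns (feature_index, threshold) or None. Thresholds are midpoints
    between consecutive distinct sorted values. Ties break toward the lowest
    feature index, then the lowest threshold (deterministic).
    """
    n = len(y)
    impurity = _IMPURITY[criterion]
    best = None
    best_score = np.inf
    onehot = np.zeros((n, n_classes))
    onehot[np.arange(n), y] = 1.0
    for j in range(X.shape[1]):
        x = X[:, j]
        order = np.argsort(x, kind="mergesort")
        xs = x[order]
        cum = np.cumsum(onehot[order], axis=0)
        total = cum[-1]
        # split after sorted position i: lt side = first i+1 samples
        valid = np.nonzero(xs[:-1] < xs[1:])[0]
        for i in valid:
            n_lt = i + 1
            n_ge = n - n_lt
            if n_lt < min_leaf or n_ge < min_leaf:
                continue
            c_lt = cum[i]
            c_ge = total - c_lt
            score = (n_lt * impurity(c_lt) + n_ge * impurity(c_ge)) / n
            if score < best_score - 1e-12:
                best_score = score
                thr = 0.5 * (xs[i] + xs[i + 1])
                best = (j, thr)
    return best


def train_tree(data: pd.DataFrame, features: Sequence[str] = DEFAULT_FEATURES,
               label_col: str = "behavior", min_leaf: int = 5,
               criterion: str = "gini", max_depth: int | None = None) -> TreeNode:
    """Grow a full classification tree on labelled standardized flakes.

    Growth stops when a node is pure, smaller than ``2 * min_leaf``, at
    ``max_depth``, or unsplittable (constant features). The fully grown tree
    classifies its training data at least as well as any trimmed subtree.
    """
    if criterion not in _IMPURITY:
        raise ParameterError(f"unknown impurity criterion {criterion!r}")
    if len(data) == 0:
        raise ParameterError("cannot train a tree on an empty dataset")
    missing = [f for f in features if f not in data.columns]
    if missing:
        raise DomainError(f"training data lacks feature columns: {missing}")
    labels = data[label_col].astype(str).to_numpy()
    classes = sorted(set(labels))
    if len(classes) < 2:
        warnings.warn("single-class training data: returning a one-leaf tree",
                      stacklevel=2)
    X = data.loc[:, list(features)].to_numpy(dtype=float)
    y = np.array([classes.index(c) for c in labels])
    counter = [0]

    def make_node(idx: np.ndarray, depth: int) -> TreeNode:
        counts = np.bincount(y[idx], minlength=len(classes)).astype(float)
        probs = counts / counts.sum()
        node = TreeNode(
            node_id=counter[0],
            n_train=len(idx),
            class_probs={c: float(p) for c, p in zip(classes, probs)},
            predicted=classes[int(np.argmax(counts))],
        )
        counter[0] += 1
        pure = counts.max() == counts.sum()
        if pure or len(idx) < 2 * min_leaf or (max_depth is not None
                                               and depth >= max_depth):
            return node
        split = _best_split(X[idx], y[idx], len(classes), min_leaf, criterion)
        if split is None:
            return node
        j, thr = split
        node.feature = features[j]
        node.threshold = float(thr)
        ge_mask = X[idx, j] >= thr
        node.ge = make_node(idx[ge_mask], depth + 1)
        node.lt = make_node(idx[~ge_mask], depth + 1)
        return node

    return make_node(np.arange(len(y)), 0)


def classify(tree: TreeNode, flake: Mapping[str, float] | pd.Series
             ) -> tuple[str, dict[str, float]]:
    """Deterministic root-to-leaf traversal of one flake.

    At each internal node the flake takes the ``ge`` branch when its feature
    value is greater than or equal to the threshold, else the ``lt`` branch.
    Returns the leaf's predicted behavior and its class-probability row.
    """
    node = tree
    while not node.is_leaf:
        try:
            value = float(flake[node.feature])
        except (KeyError, TypeError) as exc:
            raise DomainError(f"flake lacks feature {node.feature!r}") from exc
        if not np.isfinite(value):
            raise DomainError(f"flake lacks feature {node.feature!r}")
        node = node.ge if value >= node.threshold else node.lt
    return node.predicted, dict(node.class_probs)


def predict(tree: TreeNode, data: pd.DataFrame,
            pruned: frozenset[int] = frozenset()) -> np.ndarray:
    """Vectorized predictions; nodes in ``pruned`` act as leaves."""
    out = np.empty(len(data), dtype=object)
    cols: dict[str, np.ndarray] = {}

    def col(feature: str) -> np.ndarray:
        if feature not in cols:
            if feature not in data.columns:
                raise DomainError(f"data lacks feature {feature!r}")
            cols[feature] = data[feature].to_numpy(dtype=float)
        return cols[feature]

    def rec(node: TreeNode, mask: np.ndarray) -> None:
        if not mask.any():
            return
        if node.is_leaf or node.node_id in pruned:
            out[mask] = node.predicted
            return
        ge = mask & (col(node.feature) >= node.threshold)
        rec(node.ge, ge)
        rec(node.lt, mask & ~ge)

    rec(tree, np.ones(len(data), dtype=bool))
    return out.astype(str)


def _leaf_assignments(tree: TreeNode, data: pd.DataFrame) -> np.ndarray:
    """Node id of the leaf reached by each row."""
    out = np.empty(len(data), dtype=int)

    def rec(node: TreeNode, mask: np.ndarray) -> None:
        if not mask.any():
            return
        if node.is_leaf:
            out[mask] = node.node_id
            return
        ge = mask & (data[node.feature].to_numpy(dtype=float) >= node.threshold)
        rec(node.ge, ge)
        rec(node.lt, mask & ~ge)

    rec(tree, np.ones(len(data), dtype=bool))
    return out


def cost_complexity_sequence(tree: TreeNode) -> list[frozenset[int]]:
    """Weakest-link pruning: the nested sequence of pruned-node-id sets.

    The first element is the empty set (full tree); the last collapses the
    root. At each step the internal node(s) with the smallest per-leaf gain
    in training misclassification cost are collapsed.
    """

    def r_node(n: TreeNode) -> float:
        # training misclassification count if n were a leaf
        return n.n_train * (1.0 - max(n.class_probs.values()))

    pruned: set[int] = set()
    sequence = [frozenset()]

    def live_internal(n: TreeNode, acc: list[TreeNode]) -> None:
        if n.node_id in pruned or n.is_leaf:
            return
        acc.append(n)
        live_internal(n.ge, acc)
        live_internal(n.lt, acc)

    def subtree_stats(n: TreeNode) -> tuple[float, int]:
        # (misclassification cost, leaf count) of the live subtree under n
        if n.is_leaf or n.node_id in pruned:
            return r_node(n), 1
        cg, lg = subtree_stats(n.ge)
        cl, ll = subtree_stats(n.lt)
        return cg + cl, lg + ll

    while not (tree.is_leaf or tree.node_id in pruned):
        acc: list[TreeNode] = []
        live_internal(tree, acc)
        gains = []
        for n in acc:
            cost, leaves = subtree_stats(n)
            g = (r_node(n) - cost) / (leaves - 1)
            gains.append((g, n.node_id))
        g_min = min(g for g, _ in gains)
        for g, nid in gains:
            if g <= g_min + 1e-12:
                pruned.add(nid)
        sequence.append(frozenset(pruned))
    return sequence


def _materialize(tree: TreeNode, pruned: frozenset[int]) -> TreeNode:
    out = copy.deepcopy(tree)

    def rec(n: TreeNode) -> None:
        if n.node_id in pruned:
            n.feature = None
            n.threshold = None
            n.ge = None
            n.lt = None
        elif not n.is_leaf:
            rec(n.ge)
            rec(n.lt)

    rec(out)
    return out


def trim_tree(tree: TreeNode, holdout: pd.DataFrame,
              label_col: str = "behavior", reps: int = 100,
              rng: np.random.Generator | None = None,
              ) -> tuple[TreeNode, TrimCurve]:
    """Select the most economical subtree on a disjoint holdout set.

    Every candidate in the weakest-link sequence is scored by its mean
    misclassification rate over ``reps`` bootstrap subsamples of the holdout;
    the smallest tree attaining the minimum mean rate is returned.
    """
    if len(holdout) == 0:
        raise ParameterError("holdout set is empty")
    rng = np.random.default_rng(0) if rng is None else rng
    truth = holdout[label_col].astype(str).to_numpy()
    candidates = cost_complexity_sequence(tree)
    # per-sample error indicators for each candidate, computed once
    errors = np.stack([predict(tree, holdout, pruned) != truth
                       for pruned in candidates])
    n = len(truth)
    idx = rng.integers(0, n, size=(reps, n))
    rates = errors[:, idx].mean(axis=(1, 2))
    sizes = [_materialize(tree, p).n_leaves() for p in candidates]

    best_rate = rates.min()
    tied = [i for i in range(len(candidates)) if rates[i] <= best_rate + 1e-12]
    chosen = min(tied, key=lambda i: sizes[i])
    trimmed = _materialize(tree, candidates[chosen])
    curve = TrimCurve(n_leaves=sizes, rates=[float(r) for r in rates],
                      chosen_size=sizes[chosen])
    return trimmed, curve


def _leaf_labels(tree: TreeNode) -> dict[int, str]:
    """Label leaves 'A^1', 'A^2', ... in ge-first traversal order."""
    counters: dict[str, int] = {}
    labels: dict[int, str] = {}

    def rec(n: TreeNode) -> None:
        if n.is_leaf:
            short = n.predicted.replace("OB", "")
            counters[short] = counters.get(short, 0) + 1
            labels[n.node_id] = f"{short}^{counters[short]}"
        else:
            rec(n.ge)
            rec(n.lt)

    rec(tree)
    return labels


def _collect_predictions(tree: TreeNode) -> set[str]:
    if tree.is_leaf:
        return {tree.predicted}
    return _collect_predictions(tree.ge) | _collect_predictions(tree.lt)


def misclassification_matrix(tree: TreeNode, test: pd.DataFrame,
                             label_col: str = "behavior",
                             per_leaf: bool = False) -> MisclassMatrix:
    """Empirical P(true behavior | classified behavior), as percentages.

    ``test`` must be disjoint from the training and trimming sets, otherwise
    the rates understate the true misclassification. With ``per_leaf`` the
    rows are individual terminal nodes (labelled 'A^1', 'C^2', ...) rather
    than pooled classified behaviors.
    """
    if len(test) == 0:
        raise ParameterError("test set is empty")
    truth = test[label_col].astype(str).to_numpy()
    if per_leaf:
        labels = _leaf_labels(tree)
        assign = _leaf_assignments(tree, test)
        classified = np.array([labels[a] for a in assign])
        all_rows = [labels[i] for i in sorted(labels)]
    else:
        classified = predict(tree, test)
        all_rows = sorted(_collect_predictions(tree))
    counts = pd.DataFrame(0.0, index=all_rows, columns=list(BEHAVIORS))
    for c, t in zip(classified, truth):
        counts.loc[c, t] += 1
    row_sums = counts.sum(axis=1)
    table = counts.div(row_sums, axis=0) * 100.0
    undefined = [r for r in all_rows if row_sums[r] == 0]
    return MisclassMatrix(table=table, counts=counts, undefined=undefined)


# ---------------------------------------------------------------------------
# serialization

def tree_to_dict(tree: TreeNode) -> dict:
    d = {
        "node_id": tree.node_id,
        "n_train": tree.n_train,
        "predicted": tree.predicted,
        "class_probs": tree.class_probs,
    }
    if not tree.is_leaf:
        d.update(feature=tree.feature, threshold=tree.threshold,
                 ge=tree_to_dict(tree.ge), lt=tree_to_dict(tree.lt))
    return d


def tree_from_dict(d: dict) -> TreeNode:
    node = TreeNode(
        node_id=int(d["node_id"]), n_train=int(d["n_train"]),
        class_probs={k: float(v) for k, v in d["class_probs"].items()},
        predicted=str(d["predicted"]),
    )
    if "feature" in d:
        node.feature = d["feature"]
        node.threshold = float(d["threshold"])
        node.ge = tree_from_dict(d["ge"])
        node.lt = tree_from_dict(d["lt"])
    return node


def _leaf_index(tree: TreeNode) -> dict[int, TreeNode]:
    idx: dict[int, TreeNode] = {}

    def rec(n: TreeNode) -> None:
        if n.is_leaf:
            idx[n.node_id] = n
        else:
            rec(n.ge)
            rec(n.lt)

    rec(tree)
    return idx


# ---------------------------------------------------------------------------
# model / results interface

class BehaviorTreeModel:
    """Classification-tree model over a labelled, standardized flake table.

    By default one tree is trained per raw material — the materials fracture
    differently and the misclassification rates are material-stratified —
    with ``per_material=False`` available for a single combined tree.

    Parameters
    ----------
    data : DataFrame
        Labelled standardized flakes (feature columns plus ``label_col``).
        Rows with an empty label are dropped.
    features : sequence of str
        Classifier features; defaults to the six standardized measures plus
        the two cortex percentages.
    """

    def __init__(self, data: pd.DataFrame,
                 features: Sequence[str] = DEFAULT_FEATURES,
                 label_col: str = "behavior", material_col: str = "material"):
        self.features = tuple(features)
        self.label_col = label_col
        self.material_col = material_col
        mask = data[label_col].notna() & (data[label_col].astype(str) != "")
        self.data = data.loc[mask].reset_index(drop=True)
        if len(self.data) == 0:
            raise ParameterError("no labelled flakes to train on")

    def fit(self, min_leaf: int = 5, criterion: str = "gini",
            trim_reps: int = 100, train_frac: float = 0.5,
            holdout_frac: float = 0.25, per_material: bool = True,
            per_leaf: bool = False, seed: int = 0) -> "BehaviorTreeResults":
        """Train, trim, and score trees; returns a results object.

        The labelled data are split (per material) into a training set, a
        trimming holdout, and a final test set used only for the
        misclassification matrix.
        """
        rng = np.random.default_rng(seed)
        groups = (
            {str(m): df for m, df in self.data.groupby(self.material_col)}
            if per_material else {"combined": self.data}
        )
        trees, curves, matrices, splits = {}, {}, {}, {}
        for material in sorted(groups):
            df = groups[material].reset_index(drop=True)
            perm = rng.permutation(len(df))
            n_train = int(round(train_frac * len(df)))
            n_hold = int(round(holdout_frac * len(df)))
            tr = df.iloc[perm[:n_train]]
            ho = df.iloc[perm[n_train:n_train + n_hold]]
            te = df.iloc[perm[n_train + n_hold:]]
            full = train_tree(tr, self.features, self.label_col,
                              min_leaf=min_leaf, criterion=criterion)
            trimmed, curve = trim_tree(full, ho, self.label_col,
                                       reps=trim_reps, rng=rng)
            mm = misclassification_matrix(trimmed, te, self.label_col,
                                          per_leaf=per_leaf)
            trees[material] = trimmed
            curves[material] = curve
            matrices[material] = mm
            splits[material] = (len(tr), len(ho), len(te))
        return BehaviorTreeResults(self, trees, curves, matrices, splits)


class BehaviorTreeResults:
    """Trimmed behavior trees with their misclassification quantification."""

    def __init__(self, model: BehaviorTreeModel | None, trees: dict,
                 curves: dict, matrices: dict, splits: dict | None = None):
        self.model = model
        self.trees = trees
        self.trim_curves = curves
        self.misclassification = matrices
        self.splits = splits or {}
        self.features = model.features if model is not None else DEFAULT_FEATURES

    def _tree_for(self, material: str) -> TreeNode:
        if material in self.trees:
            return self.trees[material]
        if "combined" in self.trees:
            return self.trees["combined"]
        raise ParameterError(f"no tree trained for material {material!r}")

    def predict(self, data: pd.DataFrame,
                material_col: str = "material") -> pd.DataFrame:
        """Classify a standardized flake table.

        Returns a copy with ``predicted_behavior`` and four class-probability
        columns appended.
        """
        out = data.copy()
        out["predicted_behavior"] = ""
        for b in BEHAVIORS:
            out[f"prob_{b}"] = np.nan
        if "combined" in self.trees:
            groups = [("combined", np.ones(len(out), dtype=bool))]
        else:
            groups = [(str(m), (out[material_col] == m).to_numpy())
                      for m in out[material_col].unique()]
        for material, mask in groups:
            if not mask.any():
                continue
            tree = self._tree_for(material)
            sub = out.loc[mask]
            out.loc[mask, "predicted_behavior"] = predict(tree, sub)
            leaf_ids = _leaf_assignments(tree, sub)
            probs = {nid: n.class_probs for nid, n in _leaf_index(tree).items()}
            for b in BEHAVIORS:
                out.loc[mask, f"prob_{b}"] = [probs[i].get(b, 0.0)
                                              for i in leaf_ids]
        return out

    def classify(self, flake: Mapping[str, float], material: str
                 ) -> tuple[str, dict[str, float]]:
        return classify(self._tree_for(material), flake)

    def summary(self) -> str:
        lines = ["Behavior classification trees", "=" * 31]
        for material, tree in self.trees.items():
            curve = self.trim_curves[material]
            mm = self.misclassification[material]
            lines.append(f"\n[{material}] leaves={tree.n_leaves()} "
                         f"depth={tree.depth()} "
                         f"(full tree had {max(curve.n_leaves)})")
            if self.splits.get(material):
                tr, ho, te = self.splits[material]
                lines.append(f"  split: train={tr} trim-holdout={ho} test={te}")
            lines.append("  P(true | classified), percent:")
            lines.append("  " + mm.table.round(1).to_string().replace("\n", "\n  "))
            if mm.undefined:
                lines.append(f"  undefined rows (never assigned): {mm.undefined}")
        return "\n".join(lines)

    def plot_trim_curve(self, material: str, ax=None):
        """Misclassification-vs-size curve for one material (needs matplotlib)."""
        import matplotlib.pyplot as plt

        curve = self.trim_curves[material]
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(curve.n_leaves, curve.rates, "o-")
        ax.axvline(curve.chosen_size, color="red", ls="--",
                   label=f"chosen size = {curve.chosen_size}")
        ax.set_xlabel("terminal nodes")
        ax.set_ylabel("holdout misclassification rate")
        ax.set_title(material)
        ax.legend()
        return ax

    def to_json(self, path) -> None:
        payload = {
            "features": list(self.features),
            "trees": {m: tree_to_dict(t) for m, t in self.trees.items()},
            "misclassification": {
                m: {"table": mm.table.to_dict(orient="index"),
                    "counts": mm.counts.to_dict(orient="index"),
                    "undefined": mm.undefined}
                for m, mm in self.misclassification.items()
            },
            "trim_curves": {
                m: {"n_leaves": c.n_leaves, "rates": c.rates,
                    "chosen_size": c.chosen_size}
                for m, c in self.trim_curves.items()
            },
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "BehaviorTreeResults":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        trees = {m: tree_from_dict(d) for m, d in payload["trees"].items()}
        matrices = {}
        for m, d in payload["misclassification"].items():
            table = pd.DataFrame.from_dict(d["table"], orient="index")[list(BEHAVIORS)]
            counts = pd.DataFrame.from_dict(d["counts"], orient="index")[list(BEHAVIORS)]
            matrices[m] = MisclassMatrix(table=table, counts=counts,
                                         undefined=list(d["undefined"]))
        curves = {m: TrimCurve(**c) for m, c in payload["trim_curves"].items()}
        out = cls(None, trees, curves, matrices)
        out.features = tuple(payload["features"])
        return out
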