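"""Optimal Prescriptive Trees trained on observational transfusion factuals.

An axis-aligned decision tree is fit on pre-operative variables only.  Each
leaf collects its members' factual treatments (bags 0-3) and estimates the
readmission rate separately per treatment arm; the leaf then *prescribes*
the arm with the lowest estimated rate (ties toward fewer bags).  Training
minimizes, over tree structures of bounded depth,

    alpha * (outcome-prediction error) + (1 - alpha) * (mean estimated
    readmission rate under the prescribed arms)

where the prediction error is the mean squared difference between each
patient's observed outcome and the arm estimate for the treatment that
patient actually received.  Both terms are rates in [0, 1]; ``alpha``
trades predictive faithfulness against prescriptive aggressiveness.

Observational data rarely populate all four arms in every leaf, so arm
estimates with fewer than ``n_arm_min`` factual patients fall back to the
parent node's estimate for that arm (recursively up to cohort-wide arm
means).

Exact optimization over trees is combinatorial; training uses the standard
practical scheme for optimal-tree objectives: greedy top-down induction
followed by a seeded local-search sweep that re-optimizes node splits
(exactly re-splitting twigs, greedily rebuilding small subtrees, and
considering collapse to a leaf) until no move improves the objective.  The
objective never increases across accepted moves, so the search terminates.
For tiny instances this recovers the exhaustive optimum, which is how the
trainer is validated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .transfusion import BAG_CHOICES

N_ARMS = len(BAG_CHOICES)
_TOL = 1e-12


@dataclass
class TreeNode:
    """Internal node (var, threshold, children) or leaf; annotated after fit."""

    var: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    # annotations (populated on the training data)
    n: int = 0
    arm_counts: list[int] = field(default_factory=lambda: [0] * N_ARMS)
    arm_estimates: list[float] = field(default_factory=lambda: [0.0] * N_ARMS)
    prescribed_arm: int = 0
    predicted_outcome: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return self.var is None

    def to_dict(self) -> dict:
        d = {
            "n": self.n,
            "arm_counts": list(map(int, self.arm_counts)),
            "arm_estimates": [float(v) for v in self.arm_estimates],
            "prescribed_arm": int(self.prescribed_arm),
            "predicted_outcome": float(self.predicted_outcome),
        }
        if not self.is_leaf:
            d.update({"var": self.var, "threshold": float(self.threshold),
                      "left": self.left.to_dict(), "right": self.right.to_dict()})
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        node = cls(n=d.get("n", 0),
                   arm_counts=list(d.get("arm_counts", [0] * N_ARMS)),
                   arm_estimates=list(d.get("arm_estimates", [0.0] * N_ARMS)),
                   prescribed_arm=d.get("prescribed_arm", 0),
                   predicted_outcome=d.get("predicted_outcome", 0.0))
        if "var" in d:
            node.var = d["var"]
            node.threshold = float(d["threshold"])
            node.left = cls.from_dict(d["left"])
            node.right = cls.from_dict(d["right"])
        return node


@dataclass
class OptObjective:
    """Objective value alpha*error + (1-alpha)*prescribed rate, both rates."""

    value: float
    error_term: float
    prescription_term: float
    alpha: float


@dataclass
class PrescriptiveTree:
    root: TreeNode
    var_names: list[str]
    max_depth: int
    min_leaf: int
    alpha: float
    n_arm_min: int
    hct_col: str | None = None
    candidate_cutoff: float = 30.0
    objective_value: float | None = None

    def prescribe(self, records: pd.DataFrame) -> np.ndarray:
        return prescribe_opt(self, records)

    # -- serialization -------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({
            "var_names": self.var_names, "max_depth": self.max_depth,
            "min_leaf": self.min_leaf, "alpha": self.alpha,
            "n_arm_min": self.n_arm_min, "hct_col": self.hct_col,
            "candidate_cutoff": self.candidate_cutoff,
            "objective_value": self.objective_value,
            "root": self.root.to_dict(),
        })

    @classmethod
    def from_json(cls, text: str) -> "PrescriptiveTree":
        d = json.loads(text)
        return cls(root=TreeNode.from_dict(d["root"]),
                   var_names=d["var_names"], max_depth=d["max_depth"],
                   min_leaf=d["min_leaf"], alpha=d["alpha"],
                   n_arm_min=d["n_arm_min"], hct_col=d.get("hct_col"),
                   candidate_cutoff=d.get("candidate_cutoff", 30.0),
                   objective_value=d.get("objective_value"))

    def render_text(self) -> str:
        lines: list[str] = []

        def walk(node: TreeNode, indent: int) -> None:
            pad = "  " * indent
            if node.is_leaf:
                lines.append(
                    f"{pad}leaf n={node.n} prescribe {node.prescribed_arm} "
                    f"bag(s), est readmission "
                    f"{node.arm_estimates[node.prescribed_arm]:.3f}")
            else:
                lines.append(f"{pad}{node.var} <= {node.threshold:.4g}")
                walk(node.left, indent + 1)
                lines.append(f"{pad}{node.var} > {node.threshold:.4g}")
                walk(node.right, indent + 1)

        walk(self.root, 0)
        return "\n".join(lines)

    def to_dot(self) -> str:
        lines = ["digraph prescriptive_tree {", "  node [shape=box];"]
        counter = [0]

        def walk(node: TreeNode) -> int:
            nid = counter[0]
            counter[0] += 1
            if node.is_leaf:
                lines.append(
                    f'  n{nid} [label="prescribe {node.prescribed_arm} bag(s)'
                    f'\\nn={node.n}", style=filled, fillcolor=lightblue];')
            else:
                lines.append(f'  n{nid} [label="{node.var} <= '
                             f'{node.threshold:.4g}"];')
                l, r = walk(node.left), walk(node.right)
                lines.append(f"  n{nid} -> n{l} [label=yes];")
                lines.append(f"  n{nid} -> n{r} [label=no];")
            return nid

        walk(self.root)
        lines.append("}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# numeric core
# ---------------------------------------------------------------------------

def _arm_stats(y: np.ndarray, bags: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    onehot = bags[:, None] == np.arange(N_ARMS)[None, :]
    counts = onehot.sum(axis=0).astype(float)
    sums = (onehot * y[:, None]).sum(axis=0).astype(float)
    return counts, sums


def _estimates(counts, sums, parent_est, n_arm_min) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1.0), 0.0)
    return np.where(counts >= n_arm_min, mean, parent_est)


def _contrib(counts, sums, parent_est, n_arm_min, alpha):
    """Un-normalized leaf contribution alpha*SSE + (1-alpha)*n*min est.

    Works on stacked candidate arrays: counts/sums of shape (..., 4).
    y is binary so sum(y^2) = sum(y) and SSE_b = s_b - 2 e_b s_b + n_b e_b^2.
    """
    est = _estimates(counts, sums, parent_est, n_arm_min)
    sse = (sums - 2 * est * sums + counts * est ** 2).sum(axis=-1)
    ntot = counts.sum(axis=-1)
    return alpha * sse + (1 - alpha) * ntot * est.min(axis=-1), est


def _candidate_thresholds(xs: np.ndarray, max_bins: int) -> np.ndarray:
    v = np.unique(xs)
    if v.size < 2:
        return np.empty(0)
    mids = (v[:-1] + v[1:]) / 2.0
    if mids.size <= max_bins:
        return mids
    pick = np.unique(np.round(
        np.linspace(0, mids.size - 1, max_bins)).astype(int))
    return mids[pick]


class _Trainer:
    def __init__(self, Xm, y, bags, var_names, max_depth, min_leaf,
                 alpha, n_arm_min, max_bins, rebuild_max_rows, rng):
        self.Xm, self.y, self.bags = Xm, y, bags
        self.var_names = var_names
        self.D, self.min_leaf, self.alpha = max_depth, min_leaf, alpha
        self.n_arm_min, self.max_bins = n_arm_min, max_bins
        self.rebuild_max_rows = rebuild_max_rows
        self.rng = rng
        counts, sums = _arm_stats(y, bags)
        overall = y.mean() if len(y) else 0.0
        with np.errstate(invalid="ignore", divide="ignore"):
            root_parent = np.where(counts > 0,
                                   sums / np.maximum(counts, 1.0), overall)
        self.root_parent_est = root_parent

    # -- split search ---------------------------------------------------
    def best_split(self, idx, parent_est):
        """Best (var_j, threshold, children contribution) at this node."""
        y, bags = self.y[idx], self.bags[idx]
        best = None
        for j in range(self.Xm.shape[1]):
            xs = self.Xm[idx, j]
            thr = _candidate_thresholds(xs, self.max_bins)
            if thr.size == 0:
                continue
            order = np.argsort(xs, kind="stable")
            xs_s = xs[order]
            onehot = (bags[order][:, None] ==
                      np.arange(N_ARMS)[None, :]).astype(float)
            cnt = np.cumsum(onehot, axis=0)
            sm = np.cumsum(onehot * y[order][:, None], axis=0)
            pos = np.searchsorted(xs_s, thr, side="right")
            ok = (pos >= self.min_leaf) & (len(idx) - pos >= self.min_leaf)
            if not ok.any():
                continue
            pos = pos[ok]
            thr_ok = thr[ok]
            lc, ls = cnt[pos - 1], sm[pos - 1]
            rc, rs = cnt[-1] - lc, sm[-1] - ls
            cl, _ = _contrib(lc, ls, parent_est, self.n_arm_min, self.alpha)
            cr, _ = _contrib(rc, rs, parent_est, self.n_arm_min, self.alpha)
            tot = cl + cr
            i = int(np.argmin(tot))
            if best is None or tot[i] < best[2] - _TOL:
                best = (j, float(thr_ok[i]), float(tot[i]))
        return best

    # -- greedy induction ----------------------------------------------
    def grow(self, idx, depth, parent_est):
        """Greedy subtree; returns (node, contribution on idx)."""
        counts, sums = _arm_stats(self.y[idx], self.bags[idx])
        leaf_contrib, est = _contrib(counts, sums, parent_est,
                                     self.n_arm_min, self.alpha)
        leaf_contrib = float(leaf_contrib)
        node = TreeNode()
        if depth < self.D and len(idx) >= 2 * self.min_leaf:
            best = self.best_split(idx, est)
            if best is not None and best[2] < leaf_contrib - _TOL:
                j, thr, _ = best
                mask = self.Xm[idx, j] <= thr
                node.var, node.threshold = self.var_names[j], thr
                node.left, cl = self.grow(idx[mask], depth + 1, est)
                node.right, cr = self.grow(idx[~mask], depth + 1, est)
                return node, cl + cr
        return node, leaf_contrib

    # -- structure evaluation --------------------------------------------
    def subtree_contrib(self, node, idx, parent_est):
        counts, sums = _arm_stats(self.y[idx], self.bags[idx])
        contrib, est = _contrib(counts, sums, parent_est,
                                self.n_arm_min, self.alpha)
        if node.is_leaf:
            return float(contrib)
        j = self.var_names.index(node.var)
        mask = self.Xm[idx, j] <= node.threshold
        return (self.subtree_contrib(node.left, idx[mask], est) +
                self.subtree_contrib(node.right, idx[~mask], est))

    # -- local search -----------------------------------------------------
    def internal_nodes(self, node, idx, parent_est, depth, out):
        if node.is_leaf:
            return
        counts, sums = _arm_stats(self.y[idx], self.bags[idx])
        est = _estimates(counts, sums, parent_est, self.n_arm_min)
        out.append((node, idx, parent_est, est, depth))
        j = self.var_names.index(node.var)
        mask = self.Xm[idx, j] <= node.threshold
        self.internal_nodes(node.left, idx[mask], est, depth + 1, out)
        self.internal_nodes(node.right, idx[~mask], est, depth + 1, out)

    def improve_node(self, node, idx, parent_est, est, depth) -> bool:
        """Try collapse / exact twig re-split / greedy rebuild; keep the best."""
        current = self.subtree_contrib(node, idx, parent_est)
        counts, sums = _arm_stats(self.y[idx], self.bags[idx])
        leaf_contrib, _ = _contrib(counts, sums, parent_est,
                                   self.n_arm_min, self.alpha)
        best_contrib = float(leaf_contrib)
        best_node = TreeNode()

        twig = node.left.is_leaf and node.right.is_leaf
        if twig:
            cand = self.best_split(idx, est)
            if cand is not None and cand[2] < best_contrib - _TOL:
                j, thr, c = cand
                best_node = TreeNode(var=self.var_names[j], threshold=thr,
                                     left=TreeNode(), right=TreeNode())
                best_contrib = c

        rem = self.D - depth
        if len(idx) <= self.rebuild_max_rows and not (twig and rem <= 1):
            for j in range(self.Xm.shape[1]):
                xs = self.Xm[idx, j]
                for thr in _candidate_thresholds(xs, self.max_bins):
                    mask = xs <= thr
                    nl, nr = int(mask.sum()), int((~mask).sum())
                    if nl < self.min_leaf or nr < self.min_leaf:
                        continue
                    left, cl = self.grow(idx[mask], depth + 1, est)
                    right, cr = self.grow(idx[~mask], depth + 1, est)
                    if cl + cr < best_contrib - _TOL:
                        best_contrib = cl + cr
                        best_node = TreeNode(var=self.var_names[j],
                                             threshold=float(thr),
                                             left=left, right=right)

        if best_contrib < current - _TOL:
            node.var, node.threshold = best_node.var, best_node.threshold
            node.left, node.right = best_node.left, best_node.right
            return True
        return False

    def local_search(self, root, idx_all, max_moves=50) -> None:
        # each iteration accepts at most one strictly improving move, then
        # re-enumerates nodes (routing below a moved node changes)
        for _ in range(max_moves):
            nodes: list = []
            self.internal_nodes(root, idx_all, self.root_parent_est, 0, nodes)
            if not nodes:
                return
            order = self.rng.permutation(len(nodes))
            improved = False
            for i in order:
                node, idx, parent_est, est, depth = nodes[i]
                if node.var is None and node.left is None:
                    continue  # collapsed by an earlier move this pass
                if self.improve_node(node, idx, parent_est, est, depth):
                    improved = True
                    break  # re-enumerate: routing below moved nodes changed
            if not improved:
                return

    # -- annotation -------------------------------------------------------
    def annotate(self, node, idx, parent_est) -> None:
        counts, sums = _arm_stats(self.y[idx], self.bags[idx])
        est = _estimates(counts, sums, parent_est, self.n_arm_min)
        node.n = int(len(idx))
        node.arm_counts = [int(c) for c in counts]
        node.arm_estimates = [float(e) for e in est]
        node.prescribed_arm = int(np.argmin(est))
        node.predicted_outcome = float(est[node.prescribed_arm])
        if not node.is_leaf:
            j = self.var_names.index(node.var)
            mask = self.Xm[idx, j] <= node.threshold
            self.annotate(node.left, idx[mask], est)
            self.annotate(node.right, idx[~mask], est)


def _prepare(X_pre, y, factual_bags):
    if isinstance(X_pre, pd.DataFrame):
        var_names = list(X_pre.columns)
        Xm = X_pre.to_numpy(dtype=float)
    else:
        Xm = np.asarray(X_pre, dtype=float)
        var_names = [f"x{j}" for j in range(Xm.shape[1])]
    y = np.asarray(y, dtype=float)
    bags = np.asarray(factual_bags, dtype=int)
    if np.isnan(Xm).any():
        raise ValueError("tree training requires complete (imputed) data")
    if not ((bags >= 0) & (bags < N_ARMS)).all():
        raise ValueError("factual bags must lie in {0, 1, 2, 3}")
    return Xm, y, bags, var_names


def train_opt(
    X_pre,
    y,
    factual_bags,
    max_depth: int = 4,
    min_leaf: int = 50,
    alpha: float = 0.5,
    seed: int = 0,
    n_arm_min: int = 10,
    max_bins: int = 32,
    rebuild_max_rows: int = 200,
    hct_col: str | None = None,
) -> PrescriptiveTree:
    """Fit a prescriptive tree on pre-operative variables and factual bags.

    Trees operate on *unscaled* values (splits are invariant to monotone
    rescaling, and raw thresholds read naturally).  Continuous variables
    with many distinct values are searched over ``max_bins`` evenly spaced
    candidate cut points; with few distinct values every midpoint between
    consecutive values is searched exactly.  ``rebuild_max_rows`` bounds
    the node size at which local search exhaustively re-splits with greedy
    subtree rebuilds.
    """
    Xm, y, bags, var_names = _prepare(X_pre, y, factual_bags)
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0, 1]")
    rng = np.random.default_rng(seed)
    tr = _Trainer(Xm, y, bags, var_names, max_depth, min_leaf, alpha,
                  n_arm_min, max_bins, rebuild_max_rows, rng)
    idx_all = np.arange(len(y))
    root, _ = tr.grow(idx_all, 0, tr.root_parent_est)
    tr.local_search(root, idx_all)
    tr.annotate(root, idx_all, tr.root_parent_est)
    tree = PrescriptiveTree(root=root, var_names=var_names,
                            max_depth=max_depth, min_leaf=min_leaf,
                            alpha=alpha, n_arm_min=n_arm_min, hct_col=hct_col)
    tree.objective_value = tree_objective(tree, X_pre, y, bags, alpha,
                                          n_arm_min).value
    return tree


def tree_objective(tree: PrescriptiveTree, X, y, factual_bags,
                   alpha: float | None = None,
                   n_arm_min: int | None = None) -> OptObjective:
    """Evaluate the tree *structure* on (X, y, bags).

    Leaf arm estimates are recomputed from the supplied data with the same
    parent-fallback rule used in training, so on the training set this
    reproduces the trained objective; it also serves as the common yardstick
    when comparing against exhaustively enumerated structures.
    """
    alpha = tree.alpha if alpha is None else alpha
    n_arm_min = tree.n_arm_min if n_arm_min is None else n_arm_min
    Xm, y, bags, _ = _prepare(X, y, factual_bags)
    n = len(y)
    counts, sums = _arm_stats(y, bags)
    overall = y.mean() if n else 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        root_parent = np.where(counts > 0, sums / np.maximum(counts, 1.0),
                               overall)
    name_to_col = {v: j for j, v in enumerate(tree.var_names)}
    err_total, presc_total = 0.0, 0.0

    def walk(node, idx, parent_est):
        nonlocal err_total, presc_total
        c, s = _arm_stats(y[idx], bags[idx])
        est = _estimates(c, s, parent_est, n_arm_min)
        if node.is_leaf:
            sse = float((s - 2 * est * s + c * est ** 2).sum())
            err_total += sse
            presc_total += float(len(idx) * est.min())
            return
        j = name_to_col[node.var]
        mask = Xm[idx, j] <= node.threshold
        walk(node.left, idx[mask], est)
        walk(node.right, idx[~mask], est)

    walk(tree.root, np.arange(n), root_parent)
    err = err_total / n
    presc = presc_total / n
    return OptObjective(value=alpha * err + (1 - alpha) * presc,
                        error_term=err, prescription_term=presc, alpha=alpha)


def prescribe_opt(tree: PrescriptiveTree, records: pd.DataFrame) -> np.ndarray:
    """Route records to leaves and return the prescribed bag counts.

    When the tree knows its HCT column, non-candidates (HCT at or above the
    cut-off) are forced to 0 bags regardless of their leaf.
    """
    n = len(records)
    bags = np.zeros(n, dtype=int)

    def walk(node, mask):
        if node.is_leaf:
            bags[mask] = node.prescribed_arm
            return
        if node.var not in records.columns:
            raise ValueError(f"record is missing split variable {node.var!r}")
        v = records[node.var].to_numpy(dtype=float)
        if np.isnan(v[mask]).any():
            raise ValueError(f"missing values in split variable {node.var!r}")
        go_left = mask & (v <= node.threshold)
        walk(node.left, go_left)
        walk(node.right, mask & ~go_left)

    walk(tree.root, np.ones(n, dtype=bool))
    if tree.hct_col is not None and tree.hct_col in records.columns:
        hct = records[tree.hct_col].to_numpy(dtype=float)
        bags[hct >= tree.candidate_cutoff] = 0
    return bags
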