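"""Per-patient maximum-parsimony trees and phylogenetic clades.

Characters are binary presence/absence per region; gains and losses both
cost 1 (Fitch).  The germline (all-absent state) roots the tree.  When the
presence patterns are pairwise compatible the perfect phylogeny is built
directly; otherwise the minimum-score topology is found by exhaustive
leaf-addition search with branch-and-bound (up to 8 regions) or a greedy
insertion + nearest-neighbour-interchange heuristic above that.

A *clade* is an edge carrying at least one mutation together with the set
of regions below it, classified trunk / branched / private exactly like
mutations.  Mutations that require more than one gain on the optimal tree
(homoplasy) are flagged and excluded from clade tabulation by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from spatialevo.variants import PresenceMatrix

# ---------------------------------------------------------------------------
# tree structure

class Node:
    """Rooted tree node; leaves carry a region label."""

    __slots__ = ("label", "children", "patterns")

    def __init__(self, label: Optional[str] = None,
                 children: Optional[List["Node"]] = None):
        self.label = label
        self.children: List[Node] = children or []
        self.patterns: List[int] = []   # pattern indices assigned to the edge above

    def is_leaf(self) -> bool:
        return not self.children

    def leaves_below(self) -> List[str]:
        if self.is_leaf():
            return [self.label]
        out: List[str] = []
        for c in self.children:
            out.extend(c.leaves_below())
        return out

    def copy(self) -> "Node":
        n = Node(self.label, [c.copy() for c in self.children])
        n.patterns = list(self.patterns)
        return n


@dataclass
class Clade:
    """An edge of the patient tree plus the regions descending from it."""

    patient: str
    regions: FrozenSet[str]
    n_regions_total: int
    n_mutations: int
    mutations: List[str]
    homoplastic: bool = False

    @property
    def cls(self) -> str:
        if len(self.regions) == self.n_regions_total:
            return "trunk"
        if len(self.regions) == 1:
            return "private"
        return "branched"

    @property
    def size(self) -> int:
        return len(self.regions)


@dataclass
class PhyloTree:
    """Rooted maximum-parsimony tree for one patient."""

    patient: str
    root: Node                       # germline; state all-absent
    regions: List[str]
    parsimony_score: int
    pattern_masks: List[int]
    pattern_mutations: List[List[str]]
    homoplastic_patterns: List[int]  # pattern indices needing >= 2 state changes
    exhaustive: bool = True

    def to_newick(self) -> str:
        def rec(node: Node) -> str:
            bl = sum(len(self.pattern_mutations[p]) for p in node.patterns)
            if node.is_leaf():
                return f"{node.label}:{bl}"
            inner = ",".join(rec(c) for c in node.children)
            return f"({inner}):{bl}"
        inner = ",".join(rec(c) for c in self.root.children)
        return f"({inner})germline:0;"

    def edge_mutation_map(self) -> Dict[str, List[str]]:
        """Leafset-keyed map of mutations per edge (for the JSON sidecar)."""
        out: Dict[str, List[str]] = {}
        def rec(node: Node):
            if node.patterns:
                key = "|".join(sorted(node.leaves_below()))
                muts = out.setdefault(key, [])
                for p in node.patterns:
                    muts.extend(self.pattern_mutations[p])
            for c in node.children:
                rec(c)
        rec(self.root)
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "patient": self.patient,
                "parsimony_score": self.parsimony_score,
                "edges": self.edge_mutation_map(),
            },
            sort_keys=True,
        )


# ---------------------------------------------------------------------------
# pattern handling

def _patterns(pm: PresenceMatrix) -> Tuple[List[int], List[int], List[List[str]], List[str]]:
    """Unique presence bitmasks, weights and mutation lists.

    Region bit order follows the sorted region list for determinism.
    """
    regions = sorted(pm.regions)
    mat = pm.matrix[regions].to_numpy(dtype=bool)
    bits = 1 << np.arange(len(regions))
    masks = (mat * bits).sum(axis=1)
    order = np.argsort(masks, kind="stable")
    uniq: List[int] = []
    weights: List[int] = []
    muts: List[List[str]] = []
    idx = pm.matrix.index.to_numpy()
    for i in order:
        m = int(masks[i])
        if uniq and uniq[-1] == m:
            weights[-1] += 1
            muts[-1].append(str(idx[i]))
        else:
            uniq.append(m)
            weights.append(1)
            muts.append([str(idx[i])])
    return uniq, weights, muts, regions


def _compatible(masks: Sequence[int]) -> bool:
    for i, a in enumerate(masks):
        for b in masks[i + 1:]:
            c = a & b
            if c and c != a and c != b:
                return False
    return True


# ---------------------------------------------------------------------------
# perfect phylogeny fast path

def _perfect_tree(masks: List[int], regions: List[str]) -> Node:
    """Laminar patterns -> tree by nesting; may be multifurcating."""
    order = sorted(range(len(masks)),
                   key=lambda i: (-bin(masks[i]).count("1"), masks[i]))
    root = Node("germline-root")
    nodes: List[Tuple[int, Node]] = []  # (mask, node) in insertion order

    def host(mask: int) -> Node:
        best = root
        best_size = len(regions) + 1  # sentinel above any pattern size
        for m, n in nodes:
            if mask & m == mask and bin(m).count("1") < best_size:
                best, best_size = n, bin(m).count("1")
        return best

    for i in order:
        n = Node()
        n.patterns.append(i)
        host(masks[i]).children.append(n)
        nodes.append((masks[i], n))
    for r, lab in enumerate(regions):
        bit = 1 << r
        h = host(bit)
        h.children.append(Node(lab))
    return root


# ---------------------------------------------------------------------------
# exhaustive search (Fitch + branch and bound)
#
# During topology enumeration the per-pattern Fitch state sets are packed
# two bits per pattern into one arbitrary-precision integer ({0} = 01,
# {1} = 10, {0,1} = 11), so a node combination is a handful of bitwise
# operations regardless of the number of patterns.

class _PackedFitch:
    def __init__(self, masks: Sequence[int], weights: Sequence[int],
                 regions: List[str]):
        P = len(masks)
        self.weights = list(weights)
        self.lo = int(sum(1 << (2 * p) for p in range(P)))  # 01 per slot
        self.all_mask = self.lo | (self.lo << 1)
        self.zero_state = self.lo                            # germline: {0}
        self.leaf_state: Dict[str, int] = {}
        for r, lab in enumerate(regions):
            st = 0
            for p, m in enumerate(masks):
                st |= (2 if (m >> r) & 1 else 1) << (2 * p)
            self.leaf_state[lab] = st

    def _combine(self, a: int, b: int):
        inter = a & b
        nonempty = (inter | (inter >> 1)) & self.lo
        empty = self.lo & ~nonempty
        if not empty:
            return inter, 0
        sel = empty | (empty << 1)
        state = (inter & ~sel) | ((a | b) & sel)
        cost = 0
        e = empty
        while e:
            lsb = e & -e
            cost += self.weights[lsb.bit_length() // 2]
            e ^= lsb
        return state, cost

    def score(self, root: Node) -> int:
        """Weighted parsimony score with the germline (all-absent) root."""
        total = 0

        def down(node: Node) -> int:
            nonlocal total
            if node.is_leaf():
                return self.leaf_state[node.label]
            acc = down(node.children[0])
            for c in node.children[1:]:
                acc, cost = self._combine(acc, down(c))
                total += cost
            return acc

        acc, cost = self._combine(down(root), self.zero_state)
        total += cost
        return total


def _fitch_score(root_children: List[Node], masks: np.ndarray,
                 weights: np.ndarray, leaf_bit: Dict[str, int],
                 per_pattern: bool = False):
    """Weighted Fitch score with the root state fixed to all-absent.

    Character state sets are coded 1 = {0}, 2 = {1}, 3 = {0,1}.  With
    ``per_pattern=True`` returns the unweighted change count per pattern.
    """
    changes = np.zeros(len(masks), dtype=np.int64)

    def down(node: Node) -> np.ndarray:
        if node.is_leaf():
            present = (masks >> leaf_bit[node.label]) & 1
            return np.where(present == 1, 2, 1).astype(np.int8)
        sets = [down(c) for c in node.children]
        acc = sets[0]
        for s in sets[1:]:
            inter = acc & s
            union = acc | s
            empty = inter == 0
            changes[:] += np.where(empty, weights, 0)
            acc = np.where(empty, union, inter).astype(np.int8)
        return acc

    root_sets = [down(c) for c in root_children]
    acc = root_sets[0]
    for s in root_sets[1:]:
        inter = acc & s
        union = acc | s
        empty = inter == 0
        changes[:] += np.where(empty, weights, 0)
        acc = np.where(empty, union, inter).astype(np.int8)
    # root is germline: state 0; one more change where 0 not in the set
    changes[:] += np.where(acc == 2, weights, 0)
    if per_pattern:
        return changes // np.maximum(weights, 1)
    return int(changes.sum())


def _enumerate_best(masks_arr: np.ndarray, weights: np.ndarray,
                    regions: List[str]) -> Node:
    """Branch-and-bound exhaustive search over rooted binary topologies.

    Leaves are inserted in sorted-label order on every edge (including
    above the root); the first topology achieving the best score is kept,
    which makes tie-breaking deterministic.
    """
    pf = _PackedFitch([int(m) for m in masks_arr], [int(w) for w in weights], regions)
    best: dict = {"score": None, "tree": None}

    def edges(node: Node, parent: Optional[Node], acc: List[Tuple[Optional[Node], Node]]):
        acc.append((parent, node))
        for c in node.children:
            edges(c, node, acc)

    def insert(root: Node, parent: Optional[Node], node: Node, leaf: Node):
        new = Node(None, [node, leaf])
        if parent is None:
            return new, new
        parent.children[parent.children.index(node)] = new
        return root, new

    def remove(parent: Optional[Node], node: Node, new: Node) -> None:
        if parent is not None:
            parent.children[parent.children.index(new)] = node

    def rec(root: Node, remaining: List[str]):
        sc = pf.score(root)
        if best["score"] is not None and remaining and sc >= best["score"]:
            # the induced-subtree score is a lower bound, and an equal-score
            # completion would lose the first-found tie-break anyway
            return
        if not remaining:
            if best["score"] is None or sc < best["score"]:
                best["score"] = sc
                best["tree"] = root.copy()
            return
        lab = remaining[0]
        rest = remaining[1:]
        acc: List[Tuple[Optional[Node], Node]] = []
        edges(root, None, acc)
        for parent, node in acc:
            leaf = Node(lab)
            new_root, new_node = insert(root, parent, node, leaf)
            rec(new_root, rest)
            remove(parent, node, new_node)

    first = Node(regions[0])
    rec(first, list(regions[1:]))
    tree = best["tree"]
    germ = Node("germline-root", [tree])
    return germ


def _edge_paths(node: Node, path: Tuple[int, ...] = ()) -> List[Tuple[int, ...]]:
    """Child-index paths identifying each edge (``()`` = above the root)."""
    out = [path]
    for i, c in enumerate(node.children):
        out.extend(_edge_paths(c, path + (i,)))
    return out


def _insert_at(root: Node, path: Tuple[int, ...], lab: str) -> Node:
    """Copy of the tree with a new leaf grafted onto the edge at ``path``."""
    root = root.copy()
    if not path:
        return Node(None, [root, Node(lab)])
    parent = root
    for i in path[:-1]:
        parent = parent.children[i]
    i = path[-1]
    parent.children[i] = Node(None, [parent.children[i], Node(lab)])
    return root


def _nni_search(masks_arr: np.ndarray, weights: np.ndarray,
                regions: List[str]) -> Node:
    """Greedy stepwise addition followed by NNI hill-climbing.

    Used above the exhaustive-regime limit; deterministic (candidate
    orders are fixed, first best kept).
    """
    pf = _PackedFitch([int(m) for m in masks_arr], [int(w) for w in weights], regions)

    def score(root: Node) -> int:
        return pf.score(root)

    root = Node(regions[0])
    for lab in regions[1:]:
        cands = [_insert_at(root, p, lab) for p in _edge_paths(root)]
        root = min(cands, key=score)

    improved = True
    while improved:
        improved = False
        base = score(root)
        for path in _edge_paths(root):
            if not path:
                continue
            parent = root
            for i in path[:-1]:
                parent = parent.children[i]
            node = parent.children[path[-1]]
            if node.is_leaf() or len(node.children) != 2 or len(parent.children) != 2:
                continue
            sib = parent.children[1 - path[-1]]
            for i_child in (0, 1):
                old_parent_children = list(parent.children)
                old_node_children = list(node.children)
                node_children = list(node.children)
                moved = node_children[i_child]
                node_children[i_child] = sib
                parent.children = [moved if c is sib else c for c in parent.children]
                node.children = node_children
                if score(root) < base:
                    base = score(root)
                    improved = True
                    break
                parent.children = old_parent_children
                node.children = old_node_children
            if improved:
                break
    return Node("germline-root", [root])


# ---------------------------------------------------------------------------
# mutation placement on the chosen topology

def _assign_patterns(germ: Node, masks: List[int], regions: List[str]) -> List[int]:
    """Place each pattern on a tree edge and flag tree-incompatible ones.

    Somatic mutations arise once and do not revert, so a pattern is *clean*
    only when one gain and no loss explain it, i.e. its Fitch minimum on
    the chosen tree is exactly one change; the defining edge is then the
    unique edge whose descendant leafset equals the pattern.  Patterns
    needing more changes (multiple gains or gain + loss) are flagged as
    homoplastic and attached to the edge covering the largest subset of
    the pattern (ties broken lexicographically).  Returns the flagged
    pattern indices.
    """
    leaf_bit = {lab: i for i, lab in enumerate(regions)}
    masks_arr = np.asarray(masks, dtype=np.int64)
    weights1 = np.ones(len(masks), dtype=np.int64)
    changes = _fitch_score(germ.children, masks_arr, weights1, leaf_bit, per_pattern=True)

    # edge catalogue: node -> leafset mask
    edges: List[Tuple[Node, int]] = []

    def rec(node: Node):
        if node is not germ:
            mask = 0
            for lab in node.leaves_below():
                mask |= 1 << leaf_bit[lab]
            edges.append((node, mask))
        for c in node.children:
            rec(c)

    rec(germ)

    def leafset_key(node: Node) -> str:
        return "|".join(sorted(node.leaves_below()))

    homoplastic: List[int] = []
    for p, mask in enumerate(masks):
        if changes[p] <= 1:
            hosts = [n for n, m in edges if m == mask]
            hosts[0].patterns.append(p)
        else:
            homoplastic.append(p)
            subs = [(n, m) for n, m in edges if m & mask == m]
            best = max(subs, key=lambda t: (bin(t[1]).count("1"),))
            cands = [n for n, m in subs if bin(m).count("1") == bin(best[1]).count("1")]
            host = min(cands, key=leafset_key)
            host.patterns.append(p)
    return homoplastic


# ---------------------------------------------------------------------------
# public operations

MAX_EXHAUSTIVE_LEAVES = 8


def build_parsimony_tree(pm: PresenceMatrix) -> PhyloTree:
    """Maximum-parsimony tree for one patient's presence matrix.

    Exhaustive (branch-and-bound) search up to 8 regions; greedy + NNI
    heuristic above.  Deterministic tie-breaking: topologies are
    enumerated in a fixed order and the first optimum is kept.
    """
    if pm.matrix.shape[0] == 0:
        raise ValueError(f"patient {pm.patient}: empty presence matrix")
    if pm.n_regions < 2:
        raise ValueError(f"patient {pm.patient}: need >= 2 regions")
    masks, weights, muts, regions = _patterns(pm)
    masks_arr = np.asarray(masks, dtype=np.int64)
    weights_arr = np.asarray(weights, dtype=np.int64)
    exhaustive = len(regions) <= MAX_EXHAUSTIVE_LEAVES

    if _compatible(masks):
        germ = _perfect_tree(masks, regions)
        # patterns are already placed on their defining edges
        score = int(weights_arr.sum())
        homoplastic: List[int] = []
    else:
        if exhaustive:
            germ = _enumerate_best(masks_arr, weights_arr, regions)
        else:
            germ = _nni_search(masks_arr, weights_arr, regions)
        leaf_bit = {lab: i for i, lab in enumerate(regions)}
        score = _fitch_score(germ.children, masks_arr, weights_arr, leaf_bit)
        homoplastic = _assign_patterns(germ, masks, regions)

    return PhyloTree(
        patient=pm.patient,
        root=germ,
        regions=regions,
        parsimony_score=score,
        pattern_masks=masks,
        pattern_mutations=muts,
        homoplastic_patterns=homoplastic,
        exhaustive=exhaustive,
    )


def map_mutations_to_clades(tree: PhyloTree) -> List[Clade]:
    """One clade per tree edge that carries at least one mutation."""
    n_total = len(tree.regions)
    clades: List[Clade] = []
    homo = set(tree.homoplastic_patterns)

    def rec(node: Node):
        if node.patterns:
            region_set = frozenset(l for l in node.leaves_below())
            for p in node.patterns:
                clades.append(
                    Clade(
                        patient=tree.patient,
                        regions=region_set,
                        n_regions_total=n_total,
                        n_mutations=len(tree.pattern_mutations[p]),
                        mutations=list(tree.pattern_mutations[p]),
                        homoplastic=p in homo,
                    )
                )
        for c in node.children:
            rec(c)

    rec(tree.root)
    # merge clades sharing an edge/region set (multiple patterns on one edge)
    merged: Dict[Tuple[FrozenSet[str], bool], Clade] = {}
    for c in clades:
        key = (c.regions, c.homoplastic)
        if key in merged:
            m = merged[key]
            m.n_mutations += c.n_mutations
            m.mutations.extend(c.mutations)
        else:
            merged[key] = c
    return sorted(
        merged.values(),
        key=lambda c: (-len(c.regions), "|".join(sorted(c.regions)), c.homoplastic),
    )


@dataclass
class CladeTable:
    """Cohort-level clade tabulation."""

    df: pd.DataFrame
    include_homoplastic: bool = False

    @property
    def class_counts(self) -> Dict[str, int]:
        vc = self.df["class"].value_counts()
        return {k: int(vc.get(k, 0)) for k in ("trunk", "branched", "private")}

    def branched_size_counts(self) -> Dict[str, int]:
        b = self.df[self.df["class"] == "branched"]
        return {
            "#2": int((b["size"] == 2).sum()),
            "#3": int((b["size"] == 3).sum()),
            "#4+": int((b["size"] >= 4).sum()),
        }

    def center_involvement_fraction(self) -> float:
        b = self.df[self.df["class"] == "branched"]
        if b.empty:
            return float("nan")
        return float(b["involves_center"].mean())

    def region_involvement(self) -> pd.Series:
        b = self.df[self.df["class"] == "branched"]
        cols = ["involves_center", "involves_upper", "involves_lower", "involves_lateral"]
        return b[cols].mean()


def tabulate_clades(
    clades_by_patient: Dict[str, List[Clade]],
    include_homoplastic: bool = False,
) -> CladeTable:
    """Flatten per-patient clades into the cohort table.

    Homoplastic clades are excluded by default; region-involvement flags
    follow the anatomical labels (T5 center, T1 upper, T3 lower, T2/T4
    lateral, LN* nodes).
    """
    rows = []
    for pat, clades in sorted(clades_by_patient.items()):
        for c in clades:
            if c.homoplastic and not include_homoplastic:
                continue
            rows.append(
                {
                    "patient": pat,
                    "regions": "|".join(sorted(c.regions)),
                    "class": c.cls,
                    "size": c.size,
                    "n_mutations": c.n_mutations,
                    "involves_center": "T5" in c.regions,
                    "involves_upper": "T1" in c.regions,
                    "involves_lower": "T3" in c.regions,
                    "involves_lateral": bool({"T2", "T4"} & c.regions),
                    "involves_ln": any(r.startswith("LN") for r in c.regions),
                    "homoplastic": c.homoplastic,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "patient", "regions", "class", "size", "n_mutations", "involves_center",
            "involves_upper", "involves_lower", "involves_lateral", "involves_ln",
            "homoplastic",
        ],
    )
    return CladeTable(df=df, include_homoplastic=include_homoplastic)
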