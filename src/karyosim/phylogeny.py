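"""Sampling of final-time cells and backward-time phylogeny reconstruction.

A subsample of cells is drawn uniformly without replacement from the final
population (hypergeometric allocation across clones).  The sampled-cell tree
is then built backward in time from the per-step, per-clone cell counts and
within-clone division counts recorded during the forward pass: at each step,
every recorded division is a candidate coalescence for the tracked ancestral
lineages of that clone (a division's two daughters are a uniform pair among
the clone's cells, so two tracked lineages coalesce with probability
``k(k-1)/(n(n-1))``); at a clone's birth its lineages re-assign to the parent
clone, coalescing with the sibling daughter's lineage where applicable.
Lineages that have not coalesced by the simulation start are joined at ``t0``
by zero-length binary splits.

Branches are annotated with the replayable CNA/driver-mutation ops separating
the clones they traverse, so that replaying root-to-tip ops reconstructs each
tip's clone genotype exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import CloneHistory

__all__ = [
    "TreeNode",
    "SampleTree",
    "sample_cells",
    "build_sample_phylogeny",
    "mrca_age",
    "clonal_ops",
]


class TreeNode:
    """Node of the sampled-cell tree.

    ``edge_ops`` are the replayable ops on the edge *above* this node, in
    forward (chronological) order.
    """

    __slots__ = ("time", "clone", "children", "edge_ops", "neutral_ops", "label")

    def __init__(self, time, clone, children=(), label=None):
        self.time = float(time)
        self.clone = clone
        self.children = list(children)
        self.edge_ops: list = []
        self.neutral_ops: list = []
        self.label = label

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self):
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(node.children)


@dataclass
class SampleTree:
    """Rooted binary tree over sampled cells, ultrametric at ``t_end``."""

    root: TreeNode
    t0: float
    t_end: float
    tips: list = field(default_factory=list)

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    def nodes(self):
        return list(self.root.walk())

    def subclonal_ops(self):
        """All ops on edges strictly below the root, flattened."""
        out = []
        for node in self.root.walk():
            if node is not self.root:
                out.extend(node.edge_ops)
        return out

    def to_newick(self) -> str:
        def rec(node, parent_time):
            bl = node.time - parent_time if not node.is_leaf else self.t_end - parent_time
            if node.is_leaf:
                return f"{node.label}:{bl:.10g}"
            inner = ",".join(rec(c, node.time) for c in node.children)
            return f"({inner})c{node.clone}:{bl:.10g}"

        if self.root.is_leaf:
            return f"{self.root.label}:0;"
        inner = ",".join(rec(c, self.root.time) for c in self.root.children)
        return f"({inner})c{self.root.clone}:0;"


def sample_cells(history: CloneHistory, n_sample: int, rng) -> dict:
    """Uniform sample without replacement of final-time cells.

    Returns ``{clone_id: sampled count}`` (hypergeometric allocation across
    clones, proportional to final cell counts).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    final = history.final_counts()
    total = sum(final.values())
    if n_sample > total:
        raise ValueError(f"n_sample {n_sample} exceeds final population {total}")
    ids = sorted(final)
    colors = np.array([final[i] for i in ids], dtype=np.int64)
    draw = rng.multivariate_hypergeometric(colors, n_sample)
    return {i: int(k) for i, k in zip(ids, draw) if k > 0}


def clonal_ops(history: CloneHistory, clone_id: int) -> list:
    """Ops on the ancestry from the initial clone to ``clone_id``, in order."""
    chain = []
    c = history.clones[clone_id]
    while c.parent is not None:
        chain.append(c.ops)
        c = history.clones[c.parent]
    out = []
    for ops in reversed(chain):
        out.extend(ops)
    return out


class _Lineage:
    __slots__ = ("node", "edge_ops")

    def __init__(self, node):
        self.node = node
        self.edge_ops: list = []


def _coalesce(a: _Lineage, b: _Lineage, time: float, clone) -> _Lineage:
    parent = TreeNode(time, clone, [a.node, b.node])
    a.node.edge_ops = list(a.edge_ops)
    b.node.edge_ops = list(b.edge_ops)
    merged = _Lineage(parent)
    return merged


def build_sample_phylogeny(history: CloneHistory, sampled: dict, rng) -> SampleTree:
    """Construct the sampled-cell phylogeny backward in time.

    ``sampled`` is the ``{clone_id: count}`` mapping from :func:`sample_cells`.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    t_end = history.t_end
    t0 = history.t0
    times = history.times
    clones = history.clones

    # validate sampled counts against final counts
    final = history.final_counts()
    for q, k in sampled.items():
        if k > final.get(q, 0):
            raise ValueError(f"sampled {k} cells from clone {q} with {final.get(q, 0)}")

    lin: dict = {}
    tips = []
    idx = 0
    for q in sorted(sampled):
        for _ in range(sampled[q]):
            node = TreeNode(t_end, q, label=f"cell{idx}")
            tips.append(node)
            lin.setdefault(q, []).append(_Lineage(node))
            idx += 1

    children_by_step = history.children_by_step()

    def n_lineages():
        return sum(len(v) for v in lin.values())

    for step in range(history.n_steps - 1, -1, -1):
        if n_lineages() <= 1:
            break
        t_lo, t_hi = float(times[step]), float(times[step + 1])
        # within-clone divisions as candidate coalescences
        for q in list(lin):
            group = lin[q]
            k = len(group)
            if k == 0:
                continue
            rec = clones[q]
            w = rec.divisions_in(step)
            if w == 0:
                continue
            n = max(rec.count_at(step + 1), k)
            if w > 0:
                # backward-ordered division times within the step
                div_times = np.sort(rng.uniform(t_lo, t_hi, size=w))[::-1]
            for ti in div_times:
                if k >= 2 and n >= 2:
                    if rng.random() * (n * (n - 1)) < k * (k - 1):
                        i, j = rng.choice(k, size=2, replace=False)
                        i, j = int(i), int(j)
                        merged = _coalesce(group[i], group[j], float(ti), q)
                        group = [g for m, g in enumerate(group) if m not in (i, j)]
                        group.append(merged)
                        k -= 1
                n = max(n - 1, k)
            lin[q] = group
        # clone foundings during this step: lineages re-assign to the parent
        handled = set()
        for cid in children_by_step.get(step, []):
            if cid in handled:
                continue
            child = clones[cid]
            parent = child.parent
            c_group = lin.pop(cid, [])
            t_birth = float(child.birth_time)
            if child.n_founded == 2:
                # both daughters founded this clone; the mother (in the
                # parent clone) was consumed, so no parent lineage can be
                # the sibling daughter
                if len(c_group) == 2:
                    merged = _coalesce(c_group[0], c_group[1], t_birth, parent)
                    c_group = [merged]
                if c_group:
                    lineage = c_group[0]
                    lineage.edge_ops = child.ops + lineage.edge_ops
                    lin.setdefault(parent, []).append(lineage)
                continue
            sib = child.sibling
            if sib is not None and clones[sib].birth_step == step:
                handled.add(sib)
                s_group = lin.pop(sib, [])
                if c_group and s_group:
                    a, b = c_group[0], s_group[0]
                    a.edge_ops = child.ops + a.edge_ops
                    b.edge_ops = clones[sib].ops + b.edge_ops
                    merged = _coalesce(a, b, t_birth, parent)
                    lin.setdefault(parent, []).append(merged)
                    continue
                survivor = c_group[0] if c_group else (s_group[0] if s_group else None)
                if survivor is not None:
                    ops = child.ops if c_group else clones[sib].ops
                    survivor.edge_ops = ops + survivor.edge_ops
                    lin.setdefault(parent, []).append(survivor)
                continue
            if not c_group:
                continue
            lineage = c_group[0]
            lineage.edge_ops = child.ops + lineage.edge_ops
            # the sibling daughter stayed in the parent clone: it may be a
            # tracked parent lineage
            p_group = lin.setdefault(parent, [])
            kp = len(p_group)
            np_ = max(clones[parent].count_at(step + 1), kp, 1)
            if kp >= 1 and rng.random() * np_ < kp:
                j = int(rng.integers(kp))
                merged = _coalesce(p_group[j], lineage, t_birth, parent)
                p_group[j] = merged
            else:
                p_group.append(lineage)

    # finalize: single lineage -> its node is the MRCA/root; otherwise join
    # leftovers at t0 with zero-length binary splits, labelled with the clone
    # the lineages occupied at t0
    remaining = [(q, g) for q in sorted(lin) for g in lin[q]]
    while len(remaining) > 1:
        qa, a = remaining.pop()
        qb, b = remaining.pop()
        remaining.append((qa, _coalesce(a, b, t0, qa)))
    _, root_lineage = remaining[0]
    root = root_lineage.node
    root.edge_ops = []
    return SampleTree(root=root, t0=t0, t_end=t_end, tips=tips)


def mrca_age(tree: SampleTree, t0: float | None = None, t_end: float | None = None) -> float:
    """MRCA age as a fraction in [-1, 0].

    0 when the MRCA coincides with sampling time; -1 when the tree only roots
    at the start of the simulation.
    """
    t0 = tree.t0 if t0 is None else t0
    t_end = tree.t_end if t_end is None else t_end
    return (tree.root.time - t_end) / (t_end - t0)
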