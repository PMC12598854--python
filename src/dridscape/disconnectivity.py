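"""Disconnectivity graphs: superbasin analysis and rendering.

Minima are grouped into superbasins at regularly spaced free-energy
thresholds (spacing ``delta``, descending from ``first``): two minima share
a superbasin at threshold E iff a path of transition states with every
barrier strictly below E connects them.  Descending through the thresholds
the superbasins split, producing the familiar tree whose leaves are vertical
lines terminating at each minimum's free energy.

The dinfo configuration dialect of disconnectionDPS is parsed for the core
keywords (DELTA, FIRST, LEVELS, MINIMA, TS); labeling/coloring extensions of
this package (LABEL_LOWEST, ORDER_PARAM, OUTPUT, FORMAT) are documented as
such.  Rendering is native (matplotlib, PostScript or SVG output) but the
min.data / ts.data inputs remain dialect-compatible, so disconnectionDPS can
be used interchangeably on the same files.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .network import KineticNetwork

__all__ = [
    "DisconnectivityConfig",
    "DisconnectivityTree",
    "TreeNode",
    "parse_dinfo",
    "read_order_parameter",
    "build_tree",
    "layout_tree",
    "render",
]

logger = logging.getLogger(__name__)

_REQUIRED_KEYWORDS = ("DELTA", "FIRST", "MINIMA", "TS")
_EXTENSION_KEYWORDS = ("LABEL_LOWEST", "ORDER_PARAM", "OUTPUT", "FORMAT")


@dataclass
class DisconnectivityConfig:
    delta: float
    first: float
    levels: int
    minima_path: str = "min.data"
    ts_path: str = "ts.data"
    label_lowest: int | None = None
    order_parameter_path: str | None = None
    output: str = "tree.svg"
    fmt: str | None = None

    def __post_init__(self):
        if self.delta <= 0:
            raise ValueError("DELTA must be > 0")
        if self.levels < 1:
            raise ValueError("LEVELS must be >= 1")


def parse_dinfo(path: str | Path) -> DisconnectivityConfig:
    """Parse a dinfo configuration file (keyword value per line, # comments)."""
    values: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        key = parts[0].upper()
        args = parts[1:]
        if key == "DELTA":
            values["delta"] = float(args[0])
        elif key == "FIRST":
            values["first"] = float(args[0])
        elif key == "LEVELS":
            values["levels"] = int(args[0])
        elif key == "MINIMA":
            values["minima_path"] = args[0]
        elif key == "TS":
            values["ts_path"] = args[0]
        elif key == "LABEL_LOWEST":
            values["label_lowest"] = int(args[0])
        elif key == "ORDER_PARAM":
            values["order_parameter_path"] = args[0]
        elif key == "OUTPUT":
            values["output"] = args[0]
        elif key == "FORMAT":
            values["fmt"] = args[0].lower()
        else:
            warnings.warn(f"dinfo line {lineno}: unknown keyword {key!r} ignored")
    missing = [k for k, attr in (("DELTA", "delta"), ("FIRST", "first"),
                                 ("MINIMA", "minima_path"), ("TS", "ts_path"))
               if attr not in values]
    if missing:
        raise ValueError(f"dinfo is missing required keyword(s): {', '.join(missing)}")
    if "levels" not in values:
        # LEVELS should be slightly larger than FIRST/DELTA; default to that
        values["levels"] = int(np.ceil(values["first"] / values["delta"])) + 1
    return DisconnectivityConfig(**values)


def read_order_parameter(path: str | Path, n_minima: int) -> np.ndarray:
    """One scalar per line, line i belonging to (1-based) minimum id i."""
    values = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        try:
            values.append(float(line))
        except ValueError as exc:
            raise ValueError(f"{path} line {lineno}: not a number: {raw!r}") from exc
    if len(values) < n_minima:
        raise ValueError(
            f"order-parameter file {path} has {len(values)} values but the "
            f"network has {n_minima} minima"
        )
    return np.asarray(values[:n_minima])


# ---------------------------------------------------------------------------
# tree construction
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    level: int
    threshold: float
    members: frozenset
    parent: "TreeNode | None" = None
    children: list = field(default_factory=list)
    terminals: list = field(default_factory=list)   # minima ending inside this node
    x: float | None = None

    def lowest(self, free_energy: np.ndarray) -> float:
        return min(free_energy[i] for i in self.members)


@dataclass
class DisconnectivityTree:
    thresholds: np.ndarray        # descending: first, first-delta, ...
    levels: list                  # levels[L] = list of TreeNode at threshold L
    free_energy: np.ndarray

    @property
    def roots(self) -> list:
        return self.levels[0]

    @property
    def n_minima(self) -> int:
        return self.free_energy.size

    def leaves(self):
        for lev in self.levels:
            for node in lev:
                for i in node.terminals:
                    yield i, node


class _UnionFind:
    def __init__(self, items):
        self.parent = {i: i for i in items}

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i, j):
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[ri] = rj


def superbasins(minima_f: np.ndarray, edges: dict, threshold: float) -> list[frozenset]:
    """Union-find superbasins at one threshold (strict '<' merging)."""
    present = [i for i in range(minima_f.size) if minima_f[i] < threshold]
    uf = _UnionFind(present)
    present_set = set(present)
    for (j, k), f_hat in edges.items():
        if f_hat < threshold and j in present_set and k in present_set:
            uf.union(j, k)
    groups: dict = {}
    for i in present:
        groups.setdefault(uf.find(i), set()).add(i)
    return [frozenset(g) for g in groups.values()]


def build_tree(net: KineticNetwork, cfg: DisconnectivityConfig) -> DisconnectivityTree:
    """Nested superbasin decomposition at thresholds first, first-delta, ...

    Barriers below an adjacent minimum (finite-sampling artifacts) are raised
    to max(F_j, F_k) plus a tiny epsilon for the merging logic only; the
    network itself is left untouched.
    """
    f = net.free_energy
    if cfg.first <= f.min():
        raise ValueError(
            f"FIRST ({cfg.first}) must lie above the global minimum ({f.min()})"
        )
    edges = dict(net.barriers)
    eps = 1e-12 * max(1.0, np.abs(f).max())
    for (j, k), f_hat in list(edges.items()):
        floor = max(f[j], f[k])
        if f_hat < floor:
            logger.info("raising barrier (%d,%d) from %g to %g for merging",
                        j, k, f_hat, floor)
            edges[(j, k)] = floor + eps

    thresholds = cfg.first - cfg.delta * np.arange(cfg.levels)
    levels: list[list[TreeNode]] = []
    for L, thr in enumerate(thresholds):
        nodes = [TreeNode(L, float(thr), members) for members in
                 sorted(superbasins(f, edges, float(thr)), key=min)]
        if L > 0:
            for node in nodes:
                probe = next(iter(node.members))
                parent = next(p for p in levels[L - 1] if probe in p.members)
                node.parent = parent
                parent.children.append(node)
        levels.append(nodes)
    # a minimum terminates inside the last node that still contains it
    carried_below = [set().union(*(n.members for n in levels[L + 1])) if L + 1 < len(levels) and levels[L + 1] else set()
                     for L in range(len(levels))]
    for L, nodes in enumerate(levels):
        for node in nodes:
            node.terminals = sorted(node.members - carried_below[L])
    return DisconnectivityTree(thresholds, levels, f.copy())


# ---------------------------------------------------------------------------
# layout & rendering
# ---------------------------------------------------------------------------

def _units(node: TreeNode, f: np.ndarray):
    """Children + terminal leaves of a node, as (sort_key, n_leaves, obj)."""
    units = []
    for child in node.children:
        units.append(((child.lowest(f), min(child.members)), len(child.members), child))
    for i in node.terminals:
        units.append((((f[i]), i), 1, ("leaf", i)))
    units.sort(key=lambda u: u[0])
    return units


def _alternate_outward(units):
    """Lowest unit central, the rest alternating right/left by energy order."""
    left, right = [], []
    for idx, u in enumerate(units[1:]):
        (right if idx % 2 == 0 else left).append(u)
    return list(reversed(left)) + [units[0]] + right if units else []


def layout_tree(tree: DisconnectivityTree) -> dict:
    """Deterministic horizontal positions in [0, 1] for every minimum.

    Within each superbasin the branch holding the lowest minimum sits in the
    middle and the remaining branches alternate outward in order of their own
    lowest energies, so funnels read as funnels.
    """
    f = tree.free_energy
    positions: dict = {}

    def place(node: TreeNode, a: float, b: float):
        node.x = 0.5 * (a + b)
        units = _alternate_outward(_units(node, f))
        total = sum(u[1] for u in units)
        if total == 0:
            return
        x = a
        for _key, weight, obj in units:
            w = (b - a) * weight / total
            if isinstance(obj, TreeNode):
                place(obj, x, x + w)
            else:
                positions[obj[1]] = x + 0.5 * w
            x += w

    roots = sorted(tree.roots, key=lambda n: (n.lowest(f), min(n.members)))
    total = sum(len(r.members) for r in roots) or 1
    # roots partition [0, 1] by leaf count, lowest-energy root central
    units = _alternate_outward(
        [((r.lowest(f), min(r.members)), len(r.members), r) for r in roots])
    x = 0.0
    for _key, weight, node in units:
        w = weight / total
        place(node, x, x + w)
        x += w
    return positions


def render(tree: DisconnectivityTree, layout: dict,
           coloring: np.ndarray | None = None,
           label_lowest: int | None = None,
           path: str | Path = "tree.svg",
           color_range: tuple[float, float] | None = None):
    """Draw the disconnectivity graph to a vector-graphics file (.svg or .ps).

    ``coloring`` maps minimum i (0-based) to an order-parameter value,
    rendered low -> blue, high -> red on each leaf segment; ``label_lowest``
    annotates the N lowest-energy minima with their 1-based ids.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib import colormaps, cm, colors as mcolors

    f = tree.free_energy
    if coloring is not None:
        coloring = np.asarray(coloring, dtype=float)
        if coloring.size < tree.n_minima:
            raise ValueError(
                f"order-parameter table has {coloring.size} entries for "
                f"{tree.n_minima} minima"
            )
        lo, hi = color_range if color_range is not None else (coloring.min(), coloring.max())
        norm = mcolors.Normalize(vmin=lo, vmax=hi if hi > lo else lo + 1.0)
        cmap = colormaps["coolwarm"]

    def leaf_color(i):
        if coloring is None:
            return "black"
        return cmap(norm(coloring[i]))

    fig, ax = plt.subplots(figsize=(6, 7))

    def node_end(child: TreeNode) -> float:
        return child.threshold

    def draw(node: TreeNode):
        units = _units(node, f)
        xs = []
        for _key, _w, obj in units:
            if isinstance(obj, TreeNode):
                xs.append(obj.x if obj.x is not None else layout[min(obj.members)])
            else:
                xs.append(layout[obj[1]])
        if len(xs) > 1:
            ax.plot([min(xs), max(xs)], [node.threshold, node.threshold],
                    color="black", lw=0.8)
        for (_key, _w, obj), x in zip(units, xs):
            if isinstance(obj, TreeNode):
                ax.plot([x, x], [node.threshold, obj.threshold], color="black", lw=0.8)
                draw(obj)
            else:
                i = obj[1]
                ax.plot([x, x], [node.threshold, f[i]], color=leaf_color(i), lw=1.2)

    for root in tree.roots:
        draw(root)

    if label_lowest:
        order = np.argsort(f, kind="stable")[:label_lowest]
        for i in order:
            ax.annotate(str(i + 1), (layout[i], f[i]), textcoords="offset points",
                        xytext=(0, -9), ha="center", fontsize=7)

    ax.set_xlim(-0.02, 1.02)
    ax.set_xticks([])
    ax.set_ylabel(r"$F$ / $k_\mathrm{B}T$")
    for side in ("top", "bottom", "right"):
        ax.spines[side].set_visible(False)
    if coloring is not None:
        fig.colorbar(cm.ScalarMappable(norm=norm, cmap=cmap), ax=ax,
                     label="order parameter", shrink=0.7)
    path = Path(path)
    fmt = path.suffix.lstrip(".") or "svg"
    save_kwargs = {}
    if fmt == "svg":
        matplotlib.rcParams["svg.hashsalt"] = "dridscape"
        save_kwargs["metadata"] = {"Date": None}  # bit-identical reruns
    fig.savefig(path, format=fmt, **save_kwargs)
    plt.close(fig)
    return path
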