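"""Lineages-Through-Time: the step function and its rendering.

Time runs forward from the root at 0 (node depth), so the series is defined
for non-ultrametric trees too, where "the present" is ambiguous; users of
backward-time conventions can negate the axis. The lineage count at time t
is the number of edges (parent, child) with depth(parent) <= t < depth(child)
— equivalently, it starts at 1 for the root, rises by c-1 at each branching
node with c children, and falls by 1 at each leaf shallower than the deepest
one. Consequently the integral of the step function over [0, t_end] equals
the total branch length of the tree exactly.

Computation (:func:`ltt`) and rendering (:func:`plot_ltt`) are separate so
the series is testable without an image pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

from .tree import Tree

__all__ = ["LTTSeries", "ltt", "plot_ltt"]


@dataclass
class LTTSeries:
    """Step function of lineage count versus time.

    ``times[i]`` is a breakpoint; ``counts[i]`` holds on
    [``times[i]``, ``times[i+1]``) and the last count holds up to ``t_end``.
    Times are strictly increasing (simultaneous events are merged into one
    breakpoint with their net change); ``t_end`` is the maximum leaf depth.
    """

    times: list[float]
    counts: list[int]
    t_end: float

    @property
    def points(self) -> list[tuple[float, int]]:
        return list(zip(self.times, self.counts))

    def count_at(self, t: float) -> int:
        """Lineage count at time ``t`` (right-continuous)."""
        if t < self.times[0] or t > self.t_end:
            raise ValueError(f"time {t} outside [{self.times[0]}, {self.t_end}]")
        count = self.counts[0]
        for bt, c in zip(self.times, self.counts):
            if bt <= t:
                count = c
            else:
                break
        return count

    def area(self) -> float:
        """Integral of the step function over [t0, t_end].

        Equals the tree's total branch length (missing lengths as 0).
        """
        total = 0.0
        for i, count in enumerate(self.counts):
            right = self.times[i + 1] if i + 1 < len(self.times) else self.t_end
            total += count * (right - self.times[i])
        return total


def ltt(tree: Tree) -> LTTSeries:
    """Compute the Lineages-Through-Time series of ``tree``."""
    deltas: dict[float, int] = {}
    t_end = 0.0
    leaf_events = []
    stack = [(tree.root, 0.0)]
    while stack:
        node, depth = stack.pop()
        if node.children:
            if len(node.children) > 1:
                deltas[depth] = deltas.get(depth, 0) + len(node.children) - 1
            for child in node.children:
                el = child.edge_length if child.edge_length is not None else 0.0
                stack.append((child, depth + el))
        else:
            leaf_events.append(depth)
            if depth > t_end:
                t_end = depth
    # leaves within floating-point noise of the deepest leaf end AT t_end
    # (path sums of equal-depth tips can differ by a few ulps)
    tol = 1e-9 * t_end
    for depth in leaf_events:
        if depth < t_end - tol:
            deltas[depth] = deltas.get(depth, 0) - 1

    times: list[float] = []
    counts: list[int] = []
    count = 1
    event_times = sorted(t for t in deltas if t < t_end or t_end == 0.0)
    if not event_times or event_times[0] > 0.0:
        times.append(0.0)
        counts.append(1)
    for t in event_times:
        count += deltas[t]
        times.append(t)
        counts.append(count)
    return LTTSeries(times=times, counts=counts, t_end=t_end)


def plot_ltt(series: LTTSeries, output_path=None, log_scale_counts: bool = False,
             color: str = "blue"):
    """Render an LTT series as a step plot; returns the matplotlib Axes.

    If ``output_path`` is given the figure is also written there (format from
    the extension). With ``log_scale_counts`` the vertical AXIS is log-scaled;
    the plotted data stay the raw counts.
    """
    if not series.times:
        raise ValueError("cannot plot an empty LTT series")
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    xs = list(series.times) + [series.t_end]
    ys = list(series.counts) + [series.counts[-1]]
    fig, ax = plt.subplots()
    ax.step(xs, ys, where="post", color=color)
    ax.set_xlabel("time (distance from root)")
    ax.set_ylabel("number of lineages")
    if log_scale_counts:
        ax.set_yscale("log")
    if output_path is not None:
        fig.savefig(output_path)
        plt.close(fig)
    return ax
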