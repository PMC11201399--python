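"""Process discovery on stage event logs: annotated directly-follows graphs.

A "process indicator" is a directly-follows graph over the stage labels
plus artificial ``start``/``end`` nodes: each patient sequence
``e1..ek`` contributes edges ``start->e1``, ``ei->e(i+1)`` and
``ek->end``.  Nodes carry absolute event frequencies and their share of
all events; edges carry absolute counts, relative frequencies and the
median/IQR of transition (sojourn) times in months.

Two relative-frequency conventions coexist in healthcare process maps
and are kept distinct here:

* **map convention** (edge annotation): edge count divided by the total
  outgoing count of its source node, so every node's out-edges sum to
  100% (the ``start`` node's out-edges then give the baseline stage
  distribution);
* **patient convention** (:func:`transition_summary`): the number of
  patients with at least one occurrence of the transition, as a
  percentage of the cohort.

Self-loops (consecutive observations in the same stage) are first-class
edges — on merged maps they are the "remained at" percentages.
Quantiles use the standard linear-interpolation definition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import networkx as nx
import numpy as np

from ckdtraj.eventlog import EventLog
from ckdtraj.staging import MERGED_STAGES, STAGES

__all__ = [
    "START",
    "END",
    "ProcessIndicator",
    "TransitionSummary",
    "discover",
    "transition_summary",
    "render_dot",
    "indicator_to_json",
]

START = "start"
END = "end"


@dataclass(frozen=True)
class ProcessIndicator:
    """Annotated directly-follows graph.

    ``graph`` is a :class:`networkx.DiGraph`; stage nodes carry
    ``count`` (event frequency) and ``rel`` (share of all events, %),
    edges carry ``count``, ``rel`` (share of source out-flow, %),
    ``median_months``/``q1_months``/``q3_months`` (None for edges
    touching start/end, whose transition time is undefined).
    """

    graph: nx.DiGraph
    n_events: int
    n_patients: int

    def edge(self, u: str, v: str) -> dict:
        return self.graph.edges[u, v]


@dataclass(frozen=True)
class TransitionSummary:
    """Patient-level summary of one directly-follows transition."""

    source: str
    target: str
    n_patients: int
    n_cohort: int
    n_occurrences: int
    pct: float
    median_months: float | None
    q1_months: float | None
    q3_months: float | None


def discover(log: EventLog) -> ProcessIndicator:
    """Build the annotated directly-follows graph of an event log."""
    if log.events.empty:
        raise ValueError("cannot discover a process from an empty log")
    g = nx.DiGraph()
    node_counts: dict[str, int] = {}
    edge_counts: dict[tuple[str, str], int] = {}
    edge_times: dict[tuple[str, str], list[float]] = {}

    for _, times, stages in log.sequences():
        path = [START, *stages, END]
        for s in stages:
            node_counts[s] = node_counts.get(s, 0) + 1
        dts = np.diff(times)
        for i, (u, v) in enumerate(zip(path[:-1], path[1:])):
            edge_counts[(u, v)] = edge_counts.get((u, v), 0) + 1
            if 1 <= i < len(path) - 2:  # event -> event edges carry a sojourn time
                edge_times.setdefault((u, v), []).append(float(dts[i - 1]))

    n_events = sum(node_counts.values())
    n_patients = log.n_patients

    g.add_node(START, count=n_patients, rel=None)
    g.add_node(END, count=n_patients, rel=None)
    for s, c in node_counts.items():
        g.add_node(s, count=c, rel=100.0 * c / n_events)

    out_totals: dict[str, int] = {}
    for (u, _), c in edge_counts.items():
        out_totals[u] = out_totals.get(u, 0) + c
    for (u, v), c in edge_counts.items():
        times = edge_times.get((u, v))
        if times:
            q1, med, q3 = np.percentile(times, [25, 50, 75])
            ann = {"median_months": float(med), "q1_months": float(q1), "q3_months": float(q3)}
        else:
            ann = {"median_months": None, "q1_months": None, "q3_months": None}
        g.add_edge(u, v, count=c, rel=100.0 * c / out_totals[u], **ann)

    return ProcessIndicator(graph=g, n_events=n_events, n_patients=n_patients)


def transition_summary(log: EventLog, source: str, target: str) -> TransitionSummary:
    """Patient-level count, percentage and pooled sojourn times of one
    directly-follows transition (``source == target`` summarises the
    self-loop, i.e. remaining in a stage between observations)."""
    n_with = 0
    times: list[float] = []
    for _, t, stages in log.sequences():
        hits = (stages[:-1] == source) & (stages[1:] == target)
        if hits.any():
            n_with += 1
            times.extend(np.diff(t)[hits].tolist())
    n_cohort = log.n_patients
    if times:
        q1, med, q3 = (float(x) for x in np.percentile(times, [25, 50, 75]))
    else:
        q1 = med = q3 = None
    return TransitionSummary(source=source, target=target, n_patients=n_with,
                             n_cohort=n_cohort, n_occurrences=len(times),
                             pct=100.0 * n_with / n_cohort,
                             median_months=med, q1_months=q1, q3_months=q3)


def _node_order(graph: nx.DiGraph) -> list[str]:
    known = [s for s in (*STAGES, *MERGED_STAGES) if s in graph]
    other = sorted(n for n in graph if n not in (*known, START, END))
    return [START, *known, *other, END]


def _shade(rel: float | None) -> str:
    """Grayscale fill: darker = more frequent (white at 0%, ~40% gray at 100%)."""
    if rel is None:
        return "#ffffff"
    level = int(round(255 - 1.55 * min(max(rel, 0.0), 100.0)))
    return f"#{level:02x}{level:02x}{level:02x}"


def render_dot(ind: ProcessIndicator) -> str:
    """Deterministic Graphviz DOT text for a process indicator.

    Stage nodes are labelled ``stage\\nrel% (abs)`` with a fill shade
    scaling with frequency; edges are labelled ``rel% | median mo``
    (median omitted where undefined).  Identical indicators yield
    byte-identical output.
    """
    g = ind.graph
    order = _node_order(g)
    lines = ["digraph process_indicator {", "  rankdir=TB;",
             '  node [shape=box, style="rounded,filled"];']
    for n in order:
        d = g.nodes[n]
        if n in (START, END):
            lines.append(f'  "{n}" [shape=circle, style=filled, fillcolor="#ffffff", '
                         f'label="{n}"];')
        else:
            label = f'{n}\\n{d["rel"]:.1f}% ({d["count"]})'
            lines.append(f'  "{n}" [fillcolor="{_shade(d["rel"])}", label="{label}"];')
    pos = {n: i for i, n in enumerate(order)}
    for u, v in sorted(g.edges, key=lambda e: (pos[e[0]], pos[e[1]])):
        d = g.edges[u, v]
        if d["median_months"] is None:
            label = f'{d["rel"]:.1f}%'
        else:
            label = f'{d["rel"]:.1f}% | {d["median_months"]:.2f} mo'
        lines.append(f'  "{u}" -> "{v}" [label="{label}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"


def indicator_to_json(ind: ProcessIndicator) -> str:
    """Stable JSON serialisation (nodes and edges in render order)."""
    g = ind.graph
    order = _node_order(g)
    pos = {n: i for i, n in enumerate(order)}
    payload = {
        "n_events": ind.n_events,
        "n_patients": ind.n_patients,
        "nodes": [{"id": n, **g.nodes[n]} for n in order],
        "edges": [{"source": u, "target": v, **g.edges[u, v]}
                  for u, v in sorted(g.edges, key=lambda e: (pos[e[0]], pos[e[1]]))],
    }
    return json.dumps(payload, indent=2)
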