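"""Minimal typed workflow engine: modules, DAG assembly, partial execution.

An analysis workflow is a directed acyclic graph of modules. Each module
declares typed input and output slots (kinds drawn from ``image``,
``labels``, ``table``) and the tunable parameters of the algorithm it wraps,
so a generic runner can validate wiring, execute nodes in topological order,
and re-run only what a parameter change invalidates.

Caching is digest-keyed: a node's cache key hashes its name, its effective
parameter values, and the digests of everything upstream, so

* an identical re-run executes zero nodes,
* changing one node's parameter re-executes exactly that node and its
  descendants, and
* requesting an intermediate output (``run_partial``) executes exactly the
  target's ancestor set — the behavior that makes interactive parameter
  tuning cheap on deep workflows.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Any, Callable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import GraphError, InputError, KindMismatchError
from .io_plate import MeasurementTable

KINDS = ("image", "labels", "table")

Slot = tuple[str, int]  # (node or workflow-input name, slot index)


@dataclass(frozen=True)
class ParamSpec:
    """Declaration of one tunable parameter of a module."""

    name: str
    kind: str  # 'int' | 'float' | 'choice'
    default: Any
    low: float | None = None
    high: float | None = None
    choices: tuple | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("int", "float", "choice"):
            raise GraphError(f"param {self.name}: unknown kind {self.kind!r}")
        try:
            self.validate(self.default)
        except InputError as exc:
            raise GraphError(f"default outside declared range: {exc}") from exc

    def validate(self, value: Any) -> Any:
        if self.kind == "choice":
            if self.choices is None or value not in self.choices:
                raise InputError(
                    f"param {self.name}: {value!r} not in choices {self.choices}"
                )
            return value
        value = int(value) if self.kind == "int" else float(value)
        if self.low is not None and value < self.low:
            raise InputError(f"param {self.name}: {value} < min {self.low}")
        if self.high is not None and value > self.high:
            raise InputError(f"param {self.name}: {value} > max {self.high}")
        return value


@dataclass(frozen=True)
class ModuleSpec:
    """Typed interface of a workflow module."""

    name: str
    input_kinds: tuple[str, ...]
    output_kinds: tuple[str, ...]
    params: tuple[ParamSpec, ...] = ()

    def __post_init__(self) -> None:
        for k in (*self.input_kinds, *self.output_kinds):
            if k not in KINDS:
                raise GraphError(f"module {self.name}: unknown kind {k!r}")
        names = [p.name for p in self.params]
        if len(names) != len(set(names)):
            raise GraphError(f"module {self.name}: duplicate param names")

    def defaults(self) -> dict[str, Any]:
        return {p.name: p.default for p in self.params}


@dataclass(frozen=True)
class Module:
    """A ModuleSpec bound to a pure function.

    ``func`` receives the inputs positionally (in ``input_kinds`` order) and
    the parameters as keywords; it must return a tuple with one value per
    output slot.
    """

    spec: ModuleSpec
    func: Callable[..., tuple]

    @property
    def name(self) -> str:
        return self.spec.name


@dataclass(frozen=True)
class WorkflowInput:
    """A declared external input of the workflow (acts as a source slot)."""

    name: str
    kind: str


@dataclass
class WorkflowGraph:
    """Validated DAG of modules with a stored topological order."""

    modules: dict[str, Module]
    inputs: dict[str, WorkflowInput]
    # (consumer name, input slot) -> (producer name, output slot); the
    # producer is either a module or a workflow input (slot 0).
    wiring: dict[Slot, Slot]
    order: list[str] = field(default_factory=list)

    def producer_kind(self, src: Slot) -> str:
        name, slot = src
        if name in self.inputs:
            return self.inputs[name].kind
        return self.modules[name].spec.output_kinds[slot]

    def node_dependencies(self, name: str) -> set[str]:
        mod = self.modules[name]
        deps = set()
        for i in range(len(mod.spec.input_kinds)):
            src_name, _ = self.wiring[(name, i)]
            if src_name in self.modules:
                deps.add(src_name)
        return deps

    def ancestors(self, name: str) -> set[str]:
        """Module ancestors of ``name``, inclusive."""
        g = self._nx()
        return nx.ancestors(g, name) | {name}

    def _nx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.modules)
        for (dst, _), (src, _) in self.wiring.items():
            if src in self.modules:
                g.add_edge(src, dst)
        return g


def build_workflow(
    modules: Sequence[Module],
    inputs: Sequence[WorkflowInput],
    edges: Sequence[tuple[Slot, Slot]],
) -> WorkflowGraph:
    """Assemble and validate a workflow graph.

    ``edges`` are ((producer, out_slot), (consumer, in_slot)) pairs; a
    producer may be a workflow input (out_slot 0). Validation checks slot
    existence, kind agreement across every edge, single-producer wiring of
    every consumed input slot, and acyclicity; the topological order is
    computed and stored on the returned graph.
    """
    mod_map = {m.name: m for m in modules}
    if len(mod_map) != len(modules):
        raise GraphError("module names must be unique within a workflow")
    in_map = {i.name: i for i in inputs}
    if set(mod_map) & set(in_map):
        raise GraphError("workflow input names collide with module names")

    wiring: dict[Slot, Slot] = {}
    for (src_name, out_slot), (dst_name, in_slot) in edges:
        if dst_name not in mod_map:
            raise GraphError(f"edge consumer {dst_name!r} is not a module")
        dst = mod_map[dst_name]
        if not 0 <= in_slot < len(dst.spec.input_kinds):
            raise GraphError(f"{dst_name} has no input slot {in_slot}")
        if src_name in mod_map:
            src_kinds = mod_map[src_name].spec.output_kinds
            if not 0 <= out_slot < len(src_kinds):
                raise GraphError(f"{src_name} has no output slot {out_slot}")
            src_kind = src_kinds[out_slot]
        elif src_name in in_map:
            if out_slot != 0:
                raise GraphError(f"workflow input {src_name!r} has only slot 0")
            src_kind = in_map[src_name].kind
        else:
            raise GraphError(f"edge producer {src_name!r} is not a module or input")
        dst_kind = dst.spec.input_kinds[in_slot]
        if src_kind != dst_kind:
            raise KindMismatchError(
                f"kind mismatch on edge ({src_name},{out_slot}) -> "
                f"({dst_name},{in_slot}): {src_kind} vs {dst_kind}"
            )
        key = (dst_name, in_slot)
        if key in wiring:
            raise GraphError(f"input slot {key} wired twice")
        wiring[key] = (src_name, out_slot)

    for name, mod in mod_map.items():
        for i in range(len(mod.spec.input_kinds)):
            if (name, i) not in wiring:
                raise GraphError(f"input slot ({name},{i}) has no producer")

    graph = WorkflowGraph(modules=mod_map, inputs=in_map, wiring=wiring)
    g = graph._nx()
    try:
        graph.order = list(nx.topological_sort(g))
    except nx.NetworkXUnfeasible:
        cycle = nx.find_cycle(g)
        raise GraphError(f"workflow contains a cycle: {cycle}") from None
    return graph


# ---------------------------------------------------------------------------
# digests
# ---------------------------------------------------------------------------


def _digest_value(value: Any) -> str:
    h = hashlib.sha1()
    if isinstance(value, np.ndarray):
        h.update(str(value.dtype).encode())
        h.update(str(value.shape).encode())
        h.update(np.ascontiguousarray(value).tobytes())
    elif isinstance(value, MeasurementTable):
        h.update(value.level.encode())
        h.update(_digest_value(value.data).encode())
    elif isinstance(value, pd.DataFrame):
        h.update(",".join(map(str, value.columns)).encode())
        h.update(pd.util.hash_pandas_object(value, index=False).values.tobytes())
    else:
        h.update(repr(value).encode())
    return h.hexdigest()


class WorkflowRunner:
    """Executes a workflow with digest-keyed caching.

    The cache dict may be shared between runners (or reused across calls on
    the same runner) to get cross-run cache hits; it maps node cache keys to
    output tuples. ``last_trace`` records the names of the nodes actually
    executed (cache hits excluded) by the most recent call, and
    ``last_params`` the effective parameter values used per node.
    """

    def __init__(self, graph: WorkflowGraph, cache: dict[str, tuple] | None = None):
        self.graph = graph
        self.cache: dict[str, tuple] = cache if cache is not None else {}
        self.last_trace: list[str] = []
        self.last_params: dict[str, dict[str, Any]] = {}

    # -- public API --------------------------------------------------------

    def run(
        self,
        inputs: Mapping[str, Any],
        param_overrides: Mapping[str, Mapping[str, Any]] | None = None,
    ) -> dict[Slot, Any]:
        """Execute every node once in topological order; return all outputs."""
        return self._execute(set(self.graph.order), inputs, param_overrides)

    def run_partial(
        self,
        target: Slot,
        inputs: Mapping[str, Any],
        param_overrides: Mapping[str, Mapping[str, Any]] | None = None,
    ) -> Any:
        """Execute exactly the ancestor set of ``target`` and return its value."""
        name, slot = target
        if name not in self.graph.modules:
            raise GraphError(f"unknown target node {name!r}")
        if not 0 <= slot < len(self.graph.modules[name].spec.output_kinds):
            raise GraphError(f"{name} has no output slot {slot}")
        needed = self.graph.ancestors(name)
        outputs = self._execute(needed, inputs, param_overrides)
        return outputs[target]

    # -- internals ---------------------------------------------------------

    def _effective_params(
        self, overrides: Mapping[str, Mapping[str, Any]] | None
    ) -> dict[str, dict[str, Any]]:
        overrides = overrides or {}
        unknown = set(overrides) - set(self.graph.modules)
        if unknown:
            raise GraphError(f"param overrides for unknown nodes: {sorted(unknown)}")
        params: dict[str, dict[str, Any]] = {}
        for name, mod in self.graph.modules.items():
            eff = mod.spec.defaults()
            declared = {p.name: p for p in mod.spec.params}
            for pname, pval in overrides.get(name, {}).items():
                if pname not in declared:
                    raise GraphError(f"node {name} declares no param {pname!r}")
                eff[pname] = declared[pname].validate(pval)
            params[name] = eff
        return params

    def _execute(
        self,
        needed: set[str],
        inputs: Mapping[str, Any],
        param_overrides: Mapping[str, Mapping[str, Any]] | None,
    ) -> dict[Slot, Any]:
        graph = self.graph
        missing = set(graph.inputs) - set(inputs)
        if missing:
            raise InputError(f"missing workflow inputs: {sorted(missing)}")
        params = self._effective_params(param_overrides)

        digests: dict[Slot, str] = {
            (name, 0): _digest_value(inputs[name]) for name in graph.inputs
        }
        values: dict[Slot, Any] = {(name, 0): inputs[name] for name in graph.inputs}

        self.last_trace = []
        self.last_params = {n: dict(params[n]) for n in graph.order if n in needed}
        outputs: dict[Slot, Any] = {}

        for name in graph.order:
            if name not in needed:
                continue
            mod = graph.modules[name]
            n_in = len(mod.spec.input_kinds)
            srcs = [graph.wiring[(name, i)] for i in range(n_in)]
            key_material = "|".join(
                [name]
                + [f"{p}={params[name][p]!r}" for p in sorted(params[name])]
                + [digests[s] for s in srcs]
            )
            key = hashlib.sha1(key_material.encode()).hexdigest()
            if key in self.cache:
                result = self.cache[key]
            else:
                args = [values[s] for s in srcs]
                try:
                    result = mod.func(*args, **params[name])
                except Exception as exc:
                    upstream = " <- ".join(s[0] for s in srcs) or "(no inputs)"
                    raise GraphError(
                        f"node {name!r} failed (inputs from {upstream}): {exc}"
                    ) from exc
                if not isinstance(result, tuple) or len(result) != len(
                    mod.spec.output_kinds
                ):
                    raise GraphError(
                        f"node {name!r} must return a tuple of "
                        f"{len(mod.spec.output_kinds)} outputs"
                    )
                self.cache[key] = result
                self.last_trace.append(name)
            for slot, value in enumerate(result):
                out = (name, slot)
                values[out] = value
                # downstream keys derive from the producing computation, not
                # from re-hashing bulky outputs
                digests[out] = hashlib.sha1(f"{key}:{slot}".encode()).hexdigest()
                outputs[out] = value
        return outputs


def run(
    graph: WorkflowGraph,
    inputs: Mapping[str, Any],
    param_overrides: Mapping[str, Mapping[str, Any]] | None = None,
    cache: dict | None = None,
) -> dict[Slot, Any]:
    """One-shot full execution (see :class:`WorkflowRunner.run`)."""
    return WorkflowRunner(graph, cache=cache).run(inputs, param_overrides)


def run_partial(
    graph: WorkflowGraph,
    target: Slot,
    inputs: Mapping[str, Any],
    param_overrides: Mapping[str, Mapping[str, Any]] | None = None,
    cache: dict | None = None,
) -> Any:
    """One-shot partial execution (see :class:`WorkflowRunner.run_partial`)."""
    return WorkflowRunner(graph, cache=cache).run_partial(target, inputs, param_overrides)
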