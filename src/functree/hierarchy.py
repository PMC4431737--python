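"""Construction, validation and (de)serialization of the Functional Tree.

The Functional Tree is a five-layer hierarchy of biological functions:

    root -> biological_category -> biological_process -> pathway -> module -> ko

The upper skeleton (pathway -> process -> category) is taken as given input.
Module placement under pathways is *inferred* from the KO inclusion
relationship between module KO sets and pathway KO sets: under the default
``subset`` policy a module is a child of every pathway whose KO set contains
the module's KO set; under the ``overlap`` policy one shared KO suffices.
A function (module, KO, even a process name reused across categories) may
therefore occur at several places in the tree: each occurrence is a
*placement* with its own placement id, while statistics downstream are keyed
by the shared function id.

KOs that belong to no module and no pathway are not dropped: they are parked
under a hidden "Undefined Biological Category" chain (category -> process ->
pathway) so that the layer ordering holds everywhere, and they keep
participating in statistical universes and normalization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .errors import HierarchyError, SchemaError

LAYERS = ("root", "biological_category", "biological_process", "pathway", "module", "ko")
LAYER_INDEX = {layer: i for i, layer in enumerate(LAYERS)}

#: layer -> layers allowed for its children
ALLOWED_CHILD_LAYERS = {
    "root": frozenset({"biological_category"}),
    "biological_category": frozenset({"biological_process"}),
    "biological_process": frozenset({"pathway"}),
    # KO directly under a pathway is legal: it belongs to the pathway but to
    # none of the modules placed under that pathway.
    "pathway": frozenset({"module", "ko"}),
    "module": frozenset({"ko"}),
    "ko": frozenset(),
}

ROOT_ID = "root"
UNDEFINED_CATEGORY_ID = "Undefined Biological Category"
UNDEFINED_PROCESS_ID = "Undefined Biological Process"
UNDEFINED_PATHWAY_ID = "Undefined Pathway"

SCHEMA_VERSION = 1

ATTACH_POLICIES = ("subset", "overlap")


@dataclass(frozen=True)
class MembershipTables:
    """Raw membership input: KO memberships plus the upper-layer skeleton.

    ko_to_modules / ko_to_pathways map a KO id to the set of modules /
    pathways it belongs to.  pathway_skeleton maps a pathway id to its
    (biological process, biological category) pair.  names maps any function
    id to a display name (ids without an entry display as themselves).
    """

    ko_to_modules: Mapping[str, frozenset[str]]
    ko_to_pathways: Mapping[str, frozenset[str]]
    pathway_skeleton: Mapping[str, tuple[str, str]]
    names: Mapping[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        if not self.ko_to_modules and not self.ko_to_pathways:
            raise HierarchyError("empty membership tables: no KO memberships given")
        missing = [p for ps in self.ko_to_pathways.values() for p in ps
                   if p not in self.pathway_skeleton]
        if missing:
            raise HierarchyError(
                "pathways missing from skeleton: %s" % ", ".join(sorted(set(missing))))
        # ids must play a single role; overlap would make the membership
        # relation self-referential/cyclic.
        kos = set(self.ko_to_modules) | set(self.ko_to_pathways)
        modules = {m for ms in self.ko_to_modules.values() for m in ms}
        pathways = set(self.pathway_skeleton) | {p for ps in self.ko_to_pathways.values() for p in ps}
        processes = {pr for pr, _ in self.pathway_skeleton.values()}
        categories = {c for _, c in self.pathway_skeleton.values()}
        roles = [("ko", kos), ("module", modules), ("pathway", pathways),
                 ("process", processes), ("category", categories)]
        for i, (role_a, ids_a) in enumerate(roles):
            for role_b, ids_b in roles[i + 1:]:
                shared = ids_a & ids_b
                if shared:
                    raise HierarchyError(
                        "cyclic/self-referential membership: ids used as both %s and %s: %s"
                        % (role_a, role_b, ", ".join(sorted(shared))))
        bad = [x for x in kos | modules | pathways | processes | categories if "/" in x]
        if bad:
            raise HierarchyError("'/' is reserved in function ids: %s" % ", ".join(sorted(bad)))

    def ko_universe(self) -> frozenset[str]:
        return frozenset(self.ko_to_modules) | frozenset(self.ko_to_pathways)


@dataclass(frozen=True)
class FunctionNode:
    """One placement of a biological function in the tree."""

    function_id: str
    placement_id: str
    layer: str
    name: str
    hidden: bool
    children: tuple[str, ...]  # placement ids, ordered


@dataclass(frozen=True)
class FunctionalTree:
    """The full hierarchy with placement/function indices.

    ``nodes`` maps placement id -> FunctionNode; ``by_function`` maps
    function id -> placements; ``by_layer`` maps layer -> function ids;
    ``leaf_ko_sets`` maps placement id -> the distinct KO *function* ids in
    that placement's subtree.
    """

    root: str
    nodes: Mapping[str, FunctionNode]
    by_function: Mapping[str, frozenset[str]] = field(compare=False)
    by_layer: Mapping[str, frozenset[str]] = field(compare=False)
    leaf_ko_sets: Mapping[str, frozenset[str]] = field(compare=False)

    # -- queries ----------------------------------------------------------
    def layer_of(self, function_id: str) -> str:
        placements = self.by_function.get(function_id)
        if not placements:
            raise HierarchyError("unknown function id: %r" % function_id)
        return self.nodes[next(iter(placements))].layer

    def function_ko_set(self, function_id: str) -> frozenset[str]:
        """Distinct KO function ids in the subtree(s) of a function."""
        placements = self.by_function.get(function_id)
        if not placements:
            raise HierarchyError("unknown function id: %r" % function_id)
        out: frozenset[str] = frozenset()
        for pid in placements:
            out |= self.leaf_ko_sets[pid]
        return out

    @property
    def ko_universe(self) -> frozenset[str]:
        return self.by_layer.get("ko", frozenset())

    def function_ids(self, layers: Iterable[str] | None = None,
                     include_root: bool = False) -> list[str]:
        layers = set(layers) if layers is not None else set(LAYERS)
        out = []
        for layer in LAYERS:
            if layer not in layers:
                continue
            for fid in sorted(self.by_layer.get(layer, ())):
                if fid == ROOT_ID and not include_root:
                    continue
                out.append(fid)
        return out

    def name_of(self, function_id: str) -> str:
        placements = self.by_function.get(function_id)
        if not placements:
            return function_id
        return self.nodes[next(iter(placements))].name

    def is_hidden_function(self, function_id: str) -> bool:
        return all(self.nodes[p].hidden for p in self.by_function[function_id])

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if self.root not in self.nodes:
            raise HierarchyError("root placement %r missing from nodes" % self.root)
        seen: set[str] = set()
        stack = [self.root]
        while stack:
            pid = stack.pop()
            if pid in seen:
                raise HierarchyError("placement %r reachable twice (cycle?)" % pid)
            seen.add(pid)
            node = self.nodes[pid]
            for cid in node.children:
                child = self.nodes.get(cid)
                if child is None:
                    raise HierarchyError("dangling child placement %r of %r" % (cid, pid))
                if child.layer not in ALLOWED_CHILD_LAYERS[node.layer]:
                    raise HierarchyError(
                        "layer order violated: %s %r under %s %r"
                        % (child.layer, child.function_id, node.layer, node.function_id))
                stack.append(cid)
        if seen != set(self.nodes):
            raise HierarchyError("unreachable placements: %s"
                                 % ", ".join(sorted(set(self.nodes) - seen)))
        # index consistency
        indexed = {p for ps in self.by_function.values() for p in ps}
        if indexed != set(self.nodes):
            raise HierarchyError("by_function index inconsistent with nodes")
        for fid, ps in self.by_function.items():
            layers = {self.nodes[p].layer for p in ps}
            if len(layers) != 1:
                raise HierarchyError("function %r placed at multiple layers: %s"
                                     % (fid, sorted(layers)))
            if any(self.nodes[p].function_id != fid for p in ps):
                raise HierarchyError("by_function index mislabels %r" % fid)
        # hidden flag: true iff Undefined category or descendant of it
        hidden_expected = self._hidden_placements()
        for pid, node in self.nodes.items():
            if node.hidden != (pid in hidden_expected):
                raise HierarchyError("hidden flag wrong on placement %r" % pid)
        # leaf-KO union property
        for pid, node in self.nodes.items():
            if node.layer == "ko":
                if self.leaf_ko_sets[pid] != frozenset({node.function_id}):
                    raise HierarchyError("KO leaf set wrong at %r" % pid)
            else:
                union: frozenset[str] = frozenset()
                for cid in node.children:
                    union |= self.leaf_ko_sets[cid]
                if self.leaf_ko_sets[pid] != union:
                    raise HierarchyError("leaf KO union property violated at %r" % pid)

    def _hidden_placements(self) -> set[str]:
        hidden: set[str] = set()
        roots = [p for p in self.by_function.get(UNDEFINED_CATEGORY_ID, frozenset())]
        stack = list(roots)
        while stack:
            pid = stack.pop()
            hidden.add(pid)
            stack.extend(self.nodes[pid].children)
        return hidden


def _index_tree(root: str, nodes: dict[str, FunctionNode]) -> FunctionalTree:
    by_function: dict[str, set[str]] = {}
    by_layer: dict[str, set[str]] = {}
    for pid, node in nodes.items():
        by_function.setdefault(node.function_id, set()).add(pid)
        by_layer.setdefault(node.layer, set()).add(node.function_id)
    leaf: dict[str, frozenset[str]] = {}

    def fill(pid: str) -> frozenset[str]:
        node = nodes[pid]
        if node.layer == "ko":
            leaf[pid] = frozenset({node.function_id})
        else:
            acc: frozenset[str] = frozenset()
            for cid in node.children:
                acc |= fill(cid)
            leaf[pid] = acc
        return leaf[pid]

    fill(root)
    return FunctionalTree(
        root=root,
        nodes=dict(nodes),
        by_function={f: frozenset(ps) for f, ps in by_function.items()},
        by_layer={l: frozenset(fs) for l, fs in by_layer.items()},
        leaf_ko_sets=leaf,
    )


def build_tree(tables: MembershipTables, attach_policy: str = "subset") -> FunctionalTree:
    """Build the Functional Tree from membership tables.

    attach_policy decides module-under-pathway placement from KO inclusion:
    ``subset`` requires KO(module) <= KO(pathway); ``overlap`` requires at
    least one shared KO (which can duplicate a module under several
    pathways).  Children are ordered lexicographically by function id, so the
    build is fully deterministic.
    """
    if attach_policy not in ATTACH_POLICIES:
        raise HierarchyError("unknown attach policy %r (expected one of %s)"
                             % (attach_policy, "/".join(ATTACH_POLICIES)))
    tables.validate()

    module_kos: dict[str, set[str]] = {}
    for ko, mods in tables.ko_to_modules.items():
        for m in mods:
            module_kos.setdefault(m, set()).add(ko)
    pathway_kos: dict[str, set[str]] = {p: set() for p in tables.pathway_skeleton}
    for ko, paths in tables.ko_to_pathways.items():
        for p in paths:
            pathway_kos.setdefault(p, set()).add(ko)

    missing_names = [m for m in module_kos if m not in tables.names]
    missing_names += [p for p in pathway_kos if p not in tables.names]
    if missing_names:
        raise HierarchyError("module/pathway ids missing from names table: %s"
                             % ", ".join(sorted(missing_names)))

    # module -> pathways it attaches under
    attachments: dict[str, list[str]] = {}
    for m, mkos in module_kos.items():
        parents = []
        for p in sorted(pathway_kos):
            pkos = pathway_kos[p]
            ok = mkos <= pkos if attach_policy == "subset" else bool(mkos & pkos)
            if ok:
                parents.append(p)
        attachments[m] = parents

    # skeleton: category -> process -> pathways
    skeleton: dict[str, dict[str, list[str]]] = {}
    for pathway, (process, category) in tables.pathway_skeleton.items():
        skeleton.setdefault(category, {}).setdefault(process, []).append(pathway)

    name = lambda fid: tables.names.get(fid, fid)
    nodes: dict[str, FunctionNode] = {}

    def add(path: tuple[str, ...], layer: str, hidden: bool,
            children: tuple[str, ...]) -> str:
        pid = "/".join(path)
        nodes[pid] = FunctionNode(function_id=path[-1], placement_id=pid, layer=layer,
                                  name=name(path[-1]), hidden=hidden, children=children)
        return pid

    def build_module(path: tuple[str, ...], m: str, hidden: bool) -> str:
        kids = tuple(add(path + (m, k), "ko", hidden, ()) for k in sorted(module_kos[m]))
        return add(path + (m,), "module", hidden, kids)

    def build_pathway(path: tuple[str, ...], p: str, hidden: bool) -> str:
        mods = sorted(m for m, parents in attachments.items() if p in parents)
        covered = set().union(*(module_kos[m] for m in mods)) if mods else set()
        direct = sorted(pathway_kos[p] - covered)
        kid_ids = sorted(mods + direct)
        kids = []
        for fid in kid_ids:
            if fid in module_kos:
                kids.append(build_module(path + (p,), fid, hidden))
            else:
                kids.append(add(path + (p, fid), "ko", hidden, ()))
        return add(path + (p,), "pathway", hidden, tuple(kids))

    category_pids = []
    for category in sorted(skeleton):
        process_pids = []
        for process in sorted(skeleton[category]):
            ppath = (ROOT_ID, category, process)
            path_pids = tuple(build_pathway(ppath, p, False)
                              for p in sorted(skeleton[category][process]))
            process_pids.append(add(ppath, "biological_process", False, path_pids))
        category_pids.append(add((ROOT_ID, category), "biological_category",
                                 False, tuple(process_pids)))

    # hidden subtree: KOs in no module and no pathway, plus modules that
    # attached to no pathway under the chosen policy
    in_module = {k for k, ms in tables.ko_to_modules.items() if ms}
    in_pathway = {k for k, ps in tables.ko_to_pathways.items() if ps}
    unassigned_kos = sorted(tables.ko_universe() - in_module - in_pathway)
    orphan_modules = sorted(m for m, parents in attachments.items() if not parents)
    if unassigned_kos or orphan_modules:
        upath = (ROOT_ID, UNDEFINED_CATEGORY_ID, UNDEFINED_PROCESS_ID, UNDEFINED_PATHWAY_ID)
        kids = []
        for fid in sorted(orphan_modules + unassigned_kos):
            if fid in module_kos:
                kids.append(build_module(upath, fid, True))
            else:
                kids.append(add(upath + (fid,), "ko", True, ()))
        upw = add(upath, "pathway", True, tuple(kids))
        upr = add(upath[:3], "biological_process", True, (upw,))
        category_pids.append(add(upath[:2], "biological_category", True, (upr,)))

    root_pid = add((ROOT_ID,), "root", False, tuple(sorted(category_pids)))
    tree = _index_tree(root_pid, nodes)
    tree.validate()
    lost = tables.ko_universe() - tree.ko_universe
    if lost:  # pragma: no cover - guarded by construction
        raise HierarchyError("KOs lost during build: %s" % ", ".join(sorted(lost)))
    return tree


# ---------------------------------------------------------------------------
# serialization

def serialize_tree(tree: FunctionalTree) -> dict:
    """Serialize to the nested-children JSON dialect (see tree_schema.json)."""

    def emit(pid: str) -> dict:
        node = tree.nodes[pid]
        return {
            "id": node.function_id,
            "name": node.name,
            "layer": node.layer,
            "hidden": node.hidden,
            "children": [emit(c) for c in node.children],
        }

    return {"schema_version": SCHEMA_VERSION, "root": emit(tree.root)}


def dumps_tree(tree: FunctionalTree) -> str:
    return json.dumps(serialize_tree(tree), indent=1, ensure_ascii=False)


_NODE_KEYS = {"id", "name", "layer", "hidden", "children"}


def load_tree(doc: dict) -> FunctionalTree:
    """Load a nested-children tree document, validating as it goes.

    Errors name the JSON path to the first violation.
    """
    if not isinstance(doc, dict):
        raise SchemaError("$: document must be a JSON object")
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise SchemaError("$.schema_version: expected %d, got %r"
                          % (SCHEMA_VERSION, doc.get("schema_version")))
    if "root" not in doc:
        raise SchemaError("$.root: missing")

    nodes: dict[str, FunctionNode] = {}

    def walk(obj: object, path: str, json_path: str,
             parent_layer: str | None, parent_hidden: bool) -> str:
        if not isinstance(obj, dict):
            raise SchemaError("%s: node must be an object" % json_path)
        extra = set(obj) - _NODE_KEYS
        if extra:
            raise SchemaError("%s: unknown keys %s" % (json_path, sorted(extra)))
        for key, typ in (("id", str), ("name", str), ("layer", str),
                         ("hidden", bool), ("children", list)):
            if key not in obj:
                raise SchemaError("%s.%s: missing" % (json_path, key))
            if not isinstance(obj[key], typ):
                raise SchemaError("%s.%s: expected %s" % (json_path, key, typ.__name__))
        layer = obj["layer"]
        if layer not in LAYERS:
            raise SchemaError("%s.layer: unknown layer %r" % (json_path, layer))
        if parent_layer is None:
            if layer != "root":
                raise SchemaError("%s.layer: top node must be 'root'" % json_path)
        elif layer not in ALLOWED_CHILD_LAYERS[parent_layer]:
            raise SchemaError("%s.layer: %r may not be a child of %r"
                              % (json_path, layer, parent_layer))
        fid = obj["id"]
        if "/" in fid:
            raise SchemaError("%s.id: '/' is reserved" % json_path)
        under_undefined = parent_hidden or (
            layer == "biological_category" and fid == UNDEFINED_CATEGORY_ID)
        if obj["hidden"] != under_undefined:
            raise SchemaError(
                "%s.hidden: must be %s (hidden iff under the Undefined Biological "
                "Category)" % (json_path, under_undefined))
        pid = path + ("/" if path else "") + fid
        if pid in nodes:
            raise SchemaError("%s: duplicate placement %r" % (json_path, pid))
        kids = tuple(
            walk(child, pid, "%s.children[%d]" % (json_path, i), layer, under_undefined)
            for i, child in enumerate(obj["children"]))
        nodes[pid] = FunctionNode(function_id=fid, placement_id=pid, layer=layer,
                                  name=obj["name"], hidden=under_undefined,
                                  children=kids)
        return pid

    root_pid = walk(doc["root"], "", "$.root", None, False)
    tree = _index_tree(root_pid, nodes)
    tree.validate()
    return tree


def loads_tree(text: str) -> FunctionalTree:
    return load_tree(json.loads(text))


def read_tree(path) -> FunctionalTree:
    with open(path, "r", encoding="utf-8") as fh:
        return load_tree(json.load(fh))


def write_tree(tree: FunctionalTree, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(dumps_tree(tree))
        fh.write("\n")


# ---------------------------------------------------------------------------
# membership table parsing (tab-separated, '#' comments)

def _data_lines(text: str):
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        yield lineno, line


def parse_pair_table(text: str) -> dict[str, frozenset[str]]:
    """Parse `child<TAB>parent` pairs into child -> set-of-parents."""
    out: dict[str, set[str]] = {}
    for lineno, line in _data_lines(text):
        fields = line.split("\t")
        if len(fields) != 2 or not all(fields):
            raise HierarchyError("line %d: expected 2 tab-separated fields" % lineno)
        out.setdefault(fields[0], set()).add(fields[1])
    return {k: frozenset(v) for k, v in out.items()}


def parse_skeleton_table(text: str) -> dict[str, tuple[str, str]]:
    """Parse `pathway<TAB>process<TAB>category` rows."""
    out: dict[str, tuple[str, str]] = {}
    for lineno, line in _data_lines(text):
        fields = line.split("\t")
        if len(fields) != 3 or not all(fields):
            raise HierarchyError("line %d: expected 3 tab-separated fields" % lineno)
        pathway, process, category = fields
        if pathway in out and out[pathway] != (process, category):
            raise HierarchyError("line %d: pathway %r re-assigned in skeleton"
                                 % (lineno, pathway))
        out[pathway] = (process, category)
    return out


def parse_names_table(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for lineno, line in _data_lines(text):
        fields = line.split("\t")
        if len(fields) != 2 or not fields[0]:
            raise HierarchyError("line %d: expected `id<TAB>name`" % lineno)
        out[fields[0]] = fields[1]
    return out


def read_membership(ko_module_path, ko_pathway_path, skeleton_path,
                    names_path, ko_list_path=None) -> MembershipTables:
    """Assemble MembershipTables from the tab-separated text interfaces.

    ko_list_path (one KO id per line, optional) extends the KO universe with
    KOs that belong to no module and no pathway — these end up under the
    hidden Undefined subtree instead of being lost.
    """
    def slurp(p):
        with open(p, "r", encoding="utf-8") as fh:
            return fh.read()

    ko_to_pathways = dict(parse_pair_table(slurp(ko_pathway_path)))
    ko_to_modules = parse_pair_table(slurp(ko_module_path))
    if ko_list_path is not None:
        for _, ko in _data_lines(slurp(ko_list_path)):
            if ko not in ko_to_pathways and ko not in ko_to_modules:
                ko_to_pathways[ko] = frozenset()
    return MembershipTables(
        ko_to_modules=ko_to_modules,
        ko_to_pathways=ko_to_pathways,
        pathway_skeleton=parse_skeleton_table(slurp(skeleton_path)),
        names=parse_names_table(slurp(names_path)),
    )
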