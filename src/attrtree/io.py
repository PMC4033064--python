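"""File formats: attribute tables (TSV/CSV), taxonomies (Newick), model
dumps and learned hierarchies (JSON), and YAML configuration."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Hashable, List, Optional, Tuple, Union

import dendropy
import numpy as np
import pandas as pd
import yaml

from .evaluation import LearnedHierarchy, Taxonomy
from .inference import McmcConfig, ModelHyper, ModelState
from .model import AttributeMatrix, NodeParams, NoiseModel, SparsityHyper
from .nodes import ROOT, NodeId, parse_path, path_str
from .tssbp import OccupancyCounts, StickState, TreeHyper

PathLike = Union[str, Path]

TREEDUMP_SCHEMA = "attrtree-treedump"
HIERARCHY_SCHEMA = "attrtree-hierarchy"

CONFIG_DEFAULTS = {
    "a": 10.0,
    "b": 5.0,
    "c_lower": 20.0,
    "c_upper": 100.0,
    "omega": 0.05,
    "alpha0": 0.05,
    "lambda": 0.2,
    "gamma": 0.05,
    "n_sweeps": 500,
    "burn_in": 250,
    "thin": 10,
    "seed": 0,
    "mh_step": 0.5,
    "theta_updates": 4,
    "c_step": 5.0,
    "resample_c": True,
    "split_merge": 10,
    "init": "root",
    "anneal_sweeps": 125,
    "anneal_c0": 2.0,
}


# ---------------------------------------------------------------- tables


def _sep_for(path: PathLike) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_attribute_table(path: PathLike) -> AttributeMatrix:
    """Read a TSV/CSV attribute table.

    Column 1 is the instance id, an optional column named ``category``
    carries labels, and every remaining column is a binary attribute.
    """
    df = pd.read_csv(path, sep=_sep_for(path))
    if df.shape[1] < 2:
        raise ValueError("attribute table needs an id column and attributes")
    id_col = df.columns[0]
    ids = [str(v) for v in df[id_col]]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate instance ids: {dupes[:5]}")
    categories = None
    attr_cols = list(df.columns[1:])
    if "category" in attr_cols:
        categories = [str(v) for v in df["category"]]
        attr_cols.remove("category")
    values = df[attr_cols].to_numpy()
    bad = ~np.isin(values, (0, 1))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"non-binary value {values[r, c]!r} at row {ids[r]!r}, "
            f"column {attr_cols[c]!r}"
        )
    return AttributeMatrix(values.astype(np.int8), ids, [str(c) for c in attr_cols], categories)


def write_attribute_table(data: AttributeMatrix, path: PathLike) -> None:
    cols: Dict[str, object] = {"instance_id": data.instance_ids}
    if data.categories is not None:
        cols["category"] = data.categories
    for d, name in enumerate(data.attribute_names):
        cols[name] = data.X[:, d]
    pd.DataFrame(cols).to_csv(path, sep=_sep_for(path), index=False)


# ------------------------------------------------------------- taxonomy


def read_taxonomy_newick(path_or_text: PathLike) -> Taxonomy:
    """Parse a Newick taxonomy; branch lengths are ignored (edge counts).

    Leaf taxon labels and internal node labels both become categories;
    duplicate labels are an error.
    """
    text = str(path_or_text)
    if not text.lstrip().startswith("(") and Path(text).exists():
        text = Path(text).read_text()
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"unparseable Newick: {exc}") from exc
    parent: Dict[Hashable, Optional[Hashable]] = {}
    category_node: Dict[str, Hashable] = {}
    index: Dict[object, int] = {}
    for i, nd in enumerate(tree.preorder_node_iter()):
        index[nd] = i
        parent[i] = index[nd.parent_node] if nd.parent_node is not None else None
        label = nd.taxon.label if nd.taxon is not None else nd.label
        if label:
            if label in category_node:
                raise ValueError(f"duplicate label {label!r} in taxonomy")
            category_node[label] = i
    if not category_node:
        raise ValueError("taxonomy has no labeled nodes")
    return Taxonomy(parent, category_node)


def write_taxonomy_newick(taxonomy: Taxonomy, path: PathLike) -> None:
    """Deterministic Newick serialization with internal labels."""
    children: Dict[Hashable, List[Hashable]] = {}
    root = None
    for n, p in taxonomy.parent.items():
        if p is None:
            root = n
        else:
            children.setdefault(p, []).append(n)
    label_of = {node: cat for cat, node in taxonomy.category_node.items()}

    def render(n: Hashable) -> str:
        kids = sorted(children.get(n, []), key=str)
        label = label_of.get(n, "")
        if not kids:
            return label
        return "(" + ",".join(render(k) for k in kids) + ")" + label

    Path(path).write_text(render(root) + ";\n")


# ------------------------------------------------------------ model dump


def _float(x: float) -> float:
    return float(x)


def tree_dump_dict(
    state: ModelState,
    data: Optional[AttributeMatrix] = None,
    seed: Optional[int] = None,
) -> dict:
    nodes = []
    children: Dict[NodeId, List[str]] = {}
    for n in sorted(state.sticks.nu):
        if n != ROOT:
            children.setdefault(n[:-1], []).append(path_str(n))
    for n in sorted(state.sticks.nu):
        nodes.append(
            {
                "id": path_str(n),
                "nu": _float(state.sticks.nu[n]),
                "theta": [_float(t) for t in state.params.theta[n]],
                "instance_count": state.counts.node(n),
                "children": children.get(n, []),
            }
        )
    sp = state.hyper.sparsity
    th = state.hyper.tree
    dump = {
        "schema": TREEDUMP_SCHEMA,
        "schema_version": 1,
        "nodes": nodes,
        "psi": {path_str(n): _float(v) for n, v in sorted(state.sticks.psi.items())},
        "assignments": {},
        "categories": {},
        "attribute_names": list(data.attribute_names) if data else [],
        "instance_order": list(data.instance_ids) if data else [],
        "hyper": {
            "a": _float(sp.a),
            "b": _float(sp.b),
            "c": [_float(v) for v in sp.c],
            "c_lower": _float(sp.c_lower),
            "c_upper": _float(sp.c_upper),
            "omega": [_float(v) for v in state.hyper.noise.omega],
            "alpha0": _float(th.alpha0),
            "lambda": _float(th.lam),
            "gamma": _float(th.gamma),
        },
        "seed": seed,
    }
    if data is not None:
        dump["assignments"] = {
            i: path_str(z) for i, z in zip(data.instance_ids, state.assignments)
        }
        if data.categories is not None:
            dump["categories"] = dict(zip(data.instance_ids, data.categories))
    return dump


def write_tree_dump(
    state: ModelState,
    path: PathLike,
    data: Optional[AttributeMatrix] = None,
    seed: Optional[int] = None,
) -> None:
    Path(path).write_text(
        json.dumps(tree_dump_dict(state, data, seed), sort_keys=True, indent=1) + "\n"
    )


def read_tree_dump(path: PathLike) -> Tuple[ModelState, dict]:
    """Reconstruct a ModelState from a dump; returns (state, raw dict)."""
    dump = json.loads(Path(path).read_text())
    if dump.get("schema") != TREEDUMP_SCHEMA:
        raise ValueError("not an attrtree tree dump")
    h = dump["hyper"]
    D = len(h["omega"])
    hyper = ModelHyper(
        tree=TreeHyper(h["alpha0"], h["lambda"], h["gamma"]),
        sparsity=SparsityHyper(
            D=D, a=h["a"], b=h["b"], c=np.asarray(h["c"]),
            c_lower=h["c_lower"], c_upper=h["c_upper"],
        ),
        noise=NoiseModel(np.asarray(h["omega"])),
    )
    sticks = StickState()
    params = NodeParams()
    for nd in dump["nodes"]:
        n = parse_path(nd["id"])
        sticks.nu[n] = nd["nu"]
        params.theta[n] = np.asarray(nd["theta"], dtype=float)
    for key, v in dump["psi"].items():
        sticks.psi[parse_path(key)] = v
    order = dump["instance_order"]
    assignments = [parse_path(dump["assignments"][i]) for i in order]
    counts = OccupancyCounts.from_assignments(assignments)
    state = ModelState(sticks, params, counts, assignments, hyper)
    return state, dump


def hierarchy_from_dump(path: PathLike) -> Tuple[LearnedHierarchy, Dict[str, str]]:
    """Load either a tree dump or a plain hierarchy JSON for scoring."""
    raw = json.loads(Path(path).read_text())
    if raw.get("schema") == TREEDUMP_SCHEMA:
        state, dump = read_tree_dump(path)
        learned = LearnedHierarchy.from_state(state, dump["instance_order"])
        return learned, dump.get("categories", {})
    if raw.get("schema") == HIERARCHY_SCHEMA:
        parent = {
            nd["id"]: nd["parent"] for nd in raw["nodes"]
        }
        return LearnedHierarchy(parent, dict(raw["node_of"])), raw.get("categories", {})
    raise ValueError("unrecognized hierarchy file")


def write_hierarchy(
    learned: LearnedHierarchy,
    path: PathLike,
    categories: Optional[Dict[str, str]] = None,
) -> None:
    label = {n: _node_label(n) for n in learned.parent}
    raw = {
        "schema": HIERARCHY_SCHEMA,
        "nodes": sorted(
            (
                {"id": label[n], "parent": label[p] if p is not None else None}
                for n, p in learned.parent.items()
            ),
            key=lambda d: d["id"],
        ),
        "node_of": {i: label[n] for i, n in sorted(learned.node_of.items())},
        "categories": dict(sorted(categories.items())) if categories else {},
    }
    Path(path).write_text(json.dumps(raw, sort_keys=True, indent=1) + "\n")


def _node_label(n: Hashable) -> str:
    if isinstance(n, tuple) and all(isinstance(v, int) for v in n):
        return "node:" + path_str(n)
    if isinstance(n, tuple):
        return "/".join(str(v) for v in n)
    return str(n)


# --------------------------------------------------------------- config


def load_config(path: Optional[PathLike] = None, **overrides) -> dict:
    """YAML config merged over the defaults (every key overridable)."""
    cfg = dict(CONFIG_DEFAULTS)
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(loaded) - set(cfg)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(loaded)
    cfg.update({k: v for k, v in overrides.items() if v is not None})
    return cfg


def hyper_from_config(cfg: dict, D: int) -> ModelHyper:
    return ModelHyper(
        tree=TreeHyper(cfg["alpha0"], cfg["lambda"], cfg["gamma"]),
        sparsity=SparsityHyper(
            D=D, a=cfg["a"], b=cfg["b"],
            c_lower=cfg["c_lower"], c_upper=cfg["c_upper"],
        ),
        noise=NoiseModel.constant(D, cfg["omega"]),
    )


def mcmc_config_from_config(cfg: dict) -> McmcConfig:
    return McmcConfig(
        n_sweeps=int(cfg["n_sweeps"]),
        burn_in=int(cfg["burn_in"]),
        thin=int(cfg["thin"]),
        seed=int(cfg["seed"]),
        mh_step=float(cfg["mh_step"]),
        theta_updates=int(cfg["theta_updates"]),
        c_step=float(cfg["c_step"]),
        resample_c=bool(cfg["resample_c"]),
        split_merge=int(cfg["split_merge"]),
        init=str(cfg["init"]),
        anneal_sweeps=int(cfg["anneal_sweeps"]),
        anneal_c0=float(cfg["anneal_c0"]),
    )
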