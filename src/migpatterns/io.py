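"""File formats and the bundled Sumba fixture.

CSV dialect throughout: comma-separated, UTF-8, header required, decimal
point.  Graph artifacts are JSON; the underlying multigraph can also be
exported as GraphML with the embedding recorded as a vertex attribute.

The Sumba fixture ships the geographic coordinates of eight populations on
the eastern Indonesian island of Sumba together with mitochondrial F_ST
gene-flow weights for the 18 edges of their spherical Delaunay
triangulation, and a relabeling table mapping population pairs to the
conventional edge labels 1..18 (recovered from the published per-population
angle identities) along with the published inner-angle values at printed
precision.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources

import networkx as nx
import pandas as pd

from .combmaps import CombinatorialMap
from .geo import DelaunayComplex, GeoPopulation

_FIXTURE_SHA256 = {
    "sumba_populations.csv": "d5dec3d6945e77db55155d0646544c0c6c5506c0ea8fb20946730b711c4fb4f2",
    "sumba_weights.csv": "4db6a380c6456b996a007a9f0951aa6e2aa1aa8b2c2b62e2b78d9d54842c9509",
    "sumba_labels.csv": "771bb548ba34c5f84ebb6141bd5fce6d30e918a48892bf93879eafbdbeab4b4d",
}


class FormatError(ValueError):
    pass


# -- CSV -----------------------------------------------------------------

def read_populations_csv(path) -> list[GeoPopulation]:
    df = pd.read_csv(path)
    required = {"name", "longitude_deg", "latitude_deg"}
    if not required <= set(df.columns):
        raise FormatError(
            f"populations CSV needs columns {sorted(required)}, got {list(df.columns)}"
        )
    return [
        GeoPopulation(str(r["name"]), float(r["longitude_deg"]), float(r["latitude_deg"]))
        for _, r in df.iterrows()
    ]


def read_weights_csv(path) -> dict[frozenset, float]:
    df = pd.read_csv(path)
    required = {"pop_a", "pop_b", "weight"}
    if not required <= set(df.columns):
        raise FormatError(
            f"weights CSV needs columns {sorted(required)}, got {list(df.columns)}"
        )
    out = {}
    for i, r in df.iterrows():
        pair = frozenset((str(r["pop_a"]), str(r["pop_b"])))
        if len(pair) != 2:
            raise FormatError(f"weights CSV line {i + 2}: pair is not two distinct names")
        if pair in out:
            raise FormatError(f"weights CSV line {i + 2}: duplicate pair {sorted(pair)}")
        out[pair] = float(r["weight"])
    return out


# -- fixture -------------------------------------------------------------

@dataclass
class FixtureBundle:
    populations: list[GeoPopulation]
    weights: dict[frozenset, float]           # name pair -> F_ST weight
    label_map: dict[frozenset, int]           # name pair -> conventional label 1..18
    printed_theta: dict[int, float]           # label -> published angle (radians)

    def weights_by_label(self) -> dict[int, float]:
        return {self.label_map[p]: w for p, w in self.weights.items()}


def load_fixture() -> FixtureBundle:
    """The Sumba tables, checksummed against the shipped files."""
    pkg = resources.files("migpatterns") / "data"
    blobs = {}
    for fname, expected in _FIXTURE_SHA256.items():
        raw = (pkg / fname).read_bytes()
        got = hashlib.sha256(raw).hexdigest()
        if got != expected:
            raise FormatError(f"fixture file {fname} is corrupted (sha256 {got})")
        blobs[fname] = raw
    with resources.as_file(pkg / "sumba_populations.csv") as p:
        populations = read_populations_csv(p)
    with resources.as_file(pkg / "sumba_weights.csv") as p:
        weights = read_weights_csv(p)
    with resources.as_file(pkg / "sumba_labels.csv") as p:
        labels = pd.read_csv(p)
    label_map = {
        frozenset((r["pop_a"], r["pop_b"])): int(r["label"]) for _, r in labels.iterrows()
    }
    printed_theta = {int(r["label"]): float(r["theta_printed"]) for _, r in labels.iterrows()}
    assert sorted(label_map.values()) == list(range(1, 19))
    return FixtureBundle(populations, weights, label_map, printed_theta)


# -- JSON artifacts ------------------------------------------------------

def complex_to_json(complex_: DelaunayComplex) -> dict:
    names = complex_.names
    return {
        "points": [
            {
                "name": p.name,
                "longitude_deg": p.longitude,
                "latitude_deg": p.latitude,
                "xyz": list(map(float, p.xyz)),
            }
            for p in complex_.populations
        ],
        "triangles": [
            {
                "ids": [names[v] for v in tri],
                "center": list(map(float, circ.center)),
                "radius": circ.radius,
            }
            for tri, circ in sorted(complex_.triangles.items())
        ],
        "edges": [
            {
                "pair": [names[i], names[j]],
                "label": lab,
                "theta": complex_.angles[lab],
            }
            for (i, j), (lab, _) in sorted(complex_.edges.items(), key=lambda kv: kv[1][0])
        ],
        "n_candidates": complex_.n_candidates,
    }


def pattern_to_json(pattern) -> dict:
    return {
        "populations": [
            {"name": p.name, "longitude_deg": p.longitude, "latitude_deg": p.latitude}
            for p in pattern.complex.populations
        ],
        "edges": [
            {
                "pair": list(pattern.edge_pops[lab]),
                "label": lab,
                "theta": pattern.theta[lab],
                "weight": pattern.weights[lab],
            }
            for lab in sorted(pattern.theta)
        ],
        "loads": {name: pattern.loads[name] for name in sorted(pattern.loads)},
    }


def report_to_json(report) -> dict:
    return {
        "face_sum_deviations": dict(sorted(report.face_sum_deviations.items())),
        "cycle_violations": [
            {"cycle": list(c), "theta_sum": s} for c, s in report.cycle_violations
        ],
        "weight_violations": list(report.weight_violations),
        "load_mismatches": dict(sorted(report.load_mismatches.items())),
        "overall": "pass" if report.overall else "fail",
    }


def map_to_json(cm: CombinatorialMap) -> dict:
    darts = cm.darts()
    out = {
        "darts": darts,
        "rotation": [cm.rotation[d] for d in darts],
        "twin": [cm.twin[d] for d in darts],
    }
    if cm.edge_labels:
        out["edge_labels"] = [cm.edge_labels.get(d) for d in darts]
    if cm.face_names:
        out["face_names"] = [cm.face_names.get(d) for d in darts]
    if cm.vertex_names:
        out["vertex_names"] = [cm.vertex_names.get(d) for d in darts]
    return out


def map_from_json(obj: dict) -> CombinatorialMap:
    darts = obj["darts"]
    rotation = dict(zip(darts, obj["rotation"]))
    twin = dict(zip(darts, obj["twin"]))
    def opt(key):
        vals = obj.get(key)
        if vals is None:
            return {}
        return {d: v for d, v in zip(darts, vals) if v is not None}
    return CombinatorialMap(rotation, twin, opt("edge_labels"),
                            opt("vertex_names"), opt("face_names"))


def polytope_to_json(P) -> dict:
    out = {
        "variables": list(P.variables),
        "A_eq": [[int(x) for x in row] for row in P.A_eq],
        "b_eq": [float(x) for x in P.b_eq],
        "bounds": [[float(lo), float(hi)] for lo, hi in P.bounds],
    }
    if P.row_names:
        out["row_names"] = list(P.row_names)
    if P.A_ub is not None and len(P.A_ub):
        out["A_ub"] = [[float(x) for x in row] for row in P.A_ub]
        out["b_ub"] = [float(x) for x in P.b_ub]
    return out


def map_to_graphml(cm: CombinatorialMap, path) -> None:
    """Export the underlying multigraph; the embedding is recorded as a
    per-vertex attribute listing the rotation (edge keys in cyclic order)."""
    g = nx.MultiGraph()
    verts = cm.vertices()
    vid = {d: i for i, v in enumerate(verts) for d in v}
    for i, v in enumerate(verts):
        rot = ",".join(str(cm.edge_labels.get(d, min(d, cm.twin[d]))) for d in v)
        g.add_node(i, rotation=rot, name=cm.vertex_names.get(v[0], ""))
    for d, t in cm.edges():
        g.add_edge(vid[d], vid[t], label=str(cm.edge_labels.get(d, d)))
    nx.write_graphml(g, path)


def dump_json(obj: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=False)
        fh.write("\n")
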