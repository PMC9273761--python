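"""End-to-end analysis pipeline and machine-readable report export."""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np

from . import __version__
from .config import PipelineConfig
from .fractal import box_counting_fd, macula_region
from .geometry import (
    classify_thick_thin,
    detect_geometry_abnormalities,
    estimate_diameters,
    extract_mask_segments,
)
from .graph import (
    assign_strahler,
    build_geometric_graph,
    detect_topology_abnormalities,
    remove_od_region,
    track_trees,
)
from .qc import detect_holes, small_components
from .skeleton import OpticDisc, detect_landmarks, skeletonize

__all__ = ["run_pipeline", "graph_to_dict", "write_graphml", "report_header"]


def report_header(config: PipelineConfig) -> dict:
    return {"vasctree_version": __version__, "config": config.to_dict()}


def graph_to_dict(g, trees=None) -> dict:
    out = {
        "vertices": {
            str(vid): {"position": list(v.position), "kind": v.kind}
            for vid, v in g.vertices.items()
        },
        "edges": {
            str(eid): {
                "endpoints": list(seg.endpoints),
                "length": seg.length,
                "pixel_path": [list(p) for p in seg.pixel_path],
            }
            for eid, seg in g.edges.items()
        },
        "defects": list(g.defects),
    }
    if trees is not None:
        out["trees"] = [
            {
                "tree_id": t.tree_id,
                "root": t.root,
                "edges": {str(e): list(uv) for e, uv in t.edges.items()},
                "strahler": {str(e): o for e, o in t.strahler.items()},
            }
            for t in trees
        ]
    return out


def write_graphml(g, path) -> None:
    nxg = nx.MultiGraph()
    for vid, v in g.vertices.items():
        nxg.add_node(vid, row=float(v.position[0]), col=float(v.position[1]),
                     kind=v.kind)
    for eid, seg in g.edges.items():
        u, v = seg.endpoints
        nxg.add_edge(u, v, key=eid, length=float(seg.length),
                     pixel_path=json.dumps([list(p) for p in seg.pixel_path]))
    nx.write_graphml(nxg, path)


def run_pipeline(
    mask: np.ndarray,
    out_dir,
    config: PipelineConfig | None = None,
    fov: np.ndarray | None = None,
    od: OpticDisc | None = None,
    macula_center: tuple[float, float] | None = None,
    artery_mask: np.ndarray | None = None,
    vein_mask: np.ndarray | None = None,
) -> dict:
    """Run skeleton -> graph -> geometry -> QC -> fractal analysis on a
    binary vessel mask and write JSON reports under ``out_dir``.

    Returns a summary dict (also written to ``summary.json``).  The QC hole
    and small-component scans run on the artery and vein masks when given,
    falling back to the binary mask otherwise.
    """
    config = config or PipelineConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    header = report_header(config)
    mask = np.asarray(mask, dtype=bool)
    if fov is None:
        fov = np.ones_like(mask)

    skel = skeletonize(mask)
    if od is not None:
        skel = remove_od_region(skel, od)
    landmarks = detect_landmarks(skel, od=od, fov=fov, delta=config.start_delta)
    g = build_geometric_graph(skel, landmarks)
    trees, orphans = track_trees(g)
    topo = detect_topology_abnormalities(g, trees, orphans)
    cyclic = {e for cyc in topo.cycles for e in cyc}
    for t in trees:
        if not (set(t.edges) & cyclic):
            assign_strahler(t)

    segments = extract_mask_segments(g, mask, od=od)
    for s in segments:
        if s.segment.pixel_path:
            estimate_diameters(s, mask)
    geom = detect_geometry_abnormalities(g, trees, segments, config.geometry)
    thickness = classify_thick_thin(segments, config.geometry)

    qc_holes, qc_small = [], []
    for sub, name in ((artery_mask, "artery"), (vein_mask, "vein")):
        if sub is not None:
            qc_holes += detect_holes(sub, od=od, mask_name=name)
            qc_small += small_components(sub, config.qc_min_area, mask_name=name)
    if artery_mask is None and vein_mask is None:
        qc_holes = detect_holes(mask, od=od, mask_name="vessel")
        qc_small = small_components(mask, config.qc_min_area, mask_name="vessel")

    fd_input = skel if config.fd_on_skeleton else mask
    fd_fov = box_counting_fd(fd_input, fov, "fov",
                             offset_average=config.fd_offset_average)
    fd_results = [fd_fov]
    if macula_center is not None:
        if od is None:
            raise ValueError("macula fractal dimension requires the optic disc")
        mac = macula_region(macula_center, od.center, mask.shape)
        fd_results.append(
            box_counting_fd(fd_input, mac, "macula",
                            offset_average=config.fd_offset_average)
        )

    (out_dir / "graph.json").write_text(
        json.dumps({**header, **graph_to_dict(g, trees)})
    )
    write_graphml(g, out_dir / "graph.graphml")
    (out_dir / "topology.json").write_text(json.dumps({
        **header,
        "overdegree_vertices": topo.overdegree_vertices,
        "cycles": topo.cycles,
        "merged_bifurcation_candidates": topo.merged_bifurcation_candidates,
        "orphan_vertices": sorted(topo.orphan_vertices),
    }))
    (out_dir / "geometry.json").write_text(json.dumps({
        **header,
        "flags": [
            {"subject": f.subject, "rule": f.rule, "value": f.value}
            for f in geom.flags
        ],
    }))
    (out_dir / "qc.json").write_text(json.dumps({
        **header,
        "holes": [
            {"area": h.area, "location": h.location, "mask": h.mask_name}
            for h in qc_holes
        ],
        "small_components": [
            {"area": c.area, "mask": c.mask_name} for c in qc_small
        ],
    }))
    (out_dir / "fd.json").write_text(json.dumps({
        **header,
        "results": [
            {"region": r.region, "fd": r.fd, "box_sizes": r.box_sizes,
             "counts": r.counts, "r_squared": r.r_squared}
            for r in fd_results
        ],
    }))
    with (out_dir / "segments.csv").open("w") as fh:
        fh.write("segment_id,tree_id,length,mean_diameter,strahler,thickness\n")
        owner = {e: t.tree_id for t in trees for e in t.edges}
        strahler = {e: t.strahler.get(e, "") for t in trees for e in t.edges}
        for s in sorted(segments, key=lambda s: s.segment_id):
            fh.write(
                f"{s.segment_id},{owner.get(s.segment_id, '')},"
                f"{s.segment.length:.3f},{s.mean_diameter:.3f},"
                f"{strahler.get(s.segment_id, '')},{thickness[s.segment_id]}\n"
            )

    summary = {
        **header,
        "n_vertices": len(g.vertices),
        "n_edges": len(g.edges),
        "n_trees": len(trees),
        "n_orphan_vertices": len(topo.orphan_vertices),
        "n_overdegree_vertices": len(topo.overdegree_vertices),
        "n_cycles": len(topo.cycles),
        "n_geometry_flags": len(geom.flags),
        "n_holes": len(qc_holes),
        "n_small_components": len(qc_small),
        "fd_fov": fd_fov.fd,
    }
    if len(fd_results) > 1:
        summary["fd_macula"] = fd_results[1].fd
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary
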