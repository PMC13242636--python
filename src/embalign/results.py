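"""JSON serialization of alignment results (for the standalone report CLI)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .atlas import AtlasSlice
from .io import CentroidRecord, ObservedFrame
from .registration import (AlignmentCandidate, CorrespondenceMatrix,
                           CostLandscape, FrameResult, RigidTransform)

RESULT_SCHEMA_VERSION = 1


def result_to_dict(res: FrameResult) -> dict:
    f = res.frame
    return {
        "schema_version": RESULT_SCHEMA_VERSION,
        "frame": {
            "embryo_id": f.embryo_id, "frame_index": f.frame_index,
            "canonical_time": f.canonical_time,
            "cells": f.cell_names,
            "positions": f.positions.tolist(),
        },
        "slice": {
            "cell_names": list(res.slice.cell_names),
            "t_start": res.slice.t_start, "t_end": res.slice.t_end,
            "t_med": res.slice.t_med,
            "means": res.slice.means.tolist(),
            "covariances": res.slice.covariances.tolist(),
        },
        "candidate": {
            "seed_angle": res.candidate.seed_angle,
            "rotation": res.candidate.transform.rotation.tolist(),
            "translation": res.candidate.transform.translation.tolist(),
            "plan": res.candidate.plan.plan.tolist(),
            "plan_converged": res.candidate.plan.converged,
            "plan_iters": res.candidate.plan.n_iters,
            "trace": list(map(float, res.candidate.trace)),
            "converged": res.candidate.converged,
        },
        "assigned_names": list(res.assigned_names),
        "assignment": res.assignment.tolist(),
        "cost_matrix": res.cost_matrix.tolist(),
        "mahalanobis": res.mahalanobis.tolist(),
        "entropies": res.entropies.tolist(),
        "total_cost": res.total_cost,
        "obs_centroid": res.obs_centroid.tolist(),
        "obs_scale": res.obs_scale,
        "ref_centroid": res.ref_centroid.tolist(),
        "ref_scale": res.ref_scale,
        "candidates": [{**c, "slice_cells": list(c["slice_cells"])}
                       for c in res.candidates],
        "landscapes": [{
            "base_rotation": ls.base_rotation.tolist(),
            "axis": ls.axis.tolist(),
            "angles": ls.angles.tolist(),
            "costs": ls.costs.tolist(),
        } for ls in res.landscapes],
        "confidences": None if res.confidences is None else np.asarray(res.confidences).tolist(),
        "frame_confidence": res.frame_confidence,
    }


def result_from_dict(d: dict) -> FrameResult:
    if d.get("schema_version") != RESULT_SCHEMA_VERSION:
        raise ValueError(f"unsupported result schema version {d.get('schema_version')!r}")
    fr = d["frame"]
    records = [CentroidRecord(fr["embryo_id"], fr["frame_index"], name, np.asarray(pos))
               for name, pos in zip(fr["cells"], fr["positions"])]
    frame = ObservedFrame(fr["embryo_id"], fr["frame_index"], records,
                          fr["canonical_time"])
    s = d["slice"]
    sl = AtlasSlice(tuple(s["cell_names"]), [], s["t_start"], s["t_end"], s["t_med"],
                    np.asarray(s["means"]), np.asarray(s["covariances"]))
    c = d["candidate"]
    cand = AlignmentCandidate(
        c["seed_angle"],
        RigidTransform(np.asarray(c["rotation"]), np.asarray(c["translation"])),
        CorrespondenceMatrix(np.asarray(c["plan"]), c["plan_converged"], c["plan_iters"]),
        list(c["trace"]), c["converged"])
    landscapes = [CostLandscape(np.asarray(ls["base_rotation"]), np.asarray(ls["axis"]),
                                np.asarray(ls["angles"]), np.asarray(ls["costs"]))
                  for ls in d["landscapes"]]
    candidates = [{**cd, "slice_cells": tuple(cd["slice_cells"])} for cd in d["candidates"]]
    return FrameResult(
        frame=frame, slice=sl, candidate=cand,
        assigned_names=list(d["assigned_names"]),
        assignment=np.asarray(d["assignment"], dtype=int),
        cost_matrix=np.asarray(d["cost_matrix"]),
        mahalanobis=np.asarray(d["mahalanobis"]),
        entropies=np.asarray(d["entropies"]),
        total_cost=d["total_cost"],
        obs_centroid=np.asarray(d["obs_centroid"]), obs_scale=d["obs_scale"],
        ref_centroid=np.asarray(d["ref_centroid"]), ref_scale=d["ref_scale"],
        candidates=candidates, landscapes=landscapes,
        confidences=None if d["confidences"] is None else np.asarray(d["confidences"]),
        frame_confidence=d["frame_confidence"])


def save_frame_result(res: FrameResult, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(result_to_dict(res), fh)


def load_frame_result(path: str | Path) -> FrameResult:
    with open(path) as fh:
        return result_from_dict(json.load(fh))
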